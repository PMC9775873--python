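"""Dataset assembly, regression fits, subject-wise cross-validation."""

import numpy as np
import pandas as pd
import pytest

from crmwave.model import (FEATURE_SETS, ModelConfig, assemble_dataset,
                           fit_model, gini_importance, predict_crm,
                           subjectwise_cv)
from crmwave.model import _partition_subjects
from crmwave.features import FEATURE_NAMES
from crmwave.postprocess import FeatureSeries
from crmwave.model import SessionFeatures


def _mock_session(subject_id, session_id=1, n=40, seed=0,
                  phase_pattern=("baseline", "depressurization",
                                 "repressurization", "recovery")):
    rng = np.random.default_rng(seed)
    times = 20.0 + 2.0 * np.arange(n)
    crm = np.clip(100.0 - rng.uniform(0, 100, size=n), 0, 100)
    values = pd.DataFrame(
        {f: rng.normal(size=n) for f in FEATURE_NAMES})
    values["hrdn"] = 0.15 + 0.001 * crm + 0.002 * rng.normal(size=n)
    valid = pd.DataFrame(True, index=range(n), columns=FEATURE_NAMES)
    series = FeatureSeries(
        window_times=times, values=values, counts=valid.astype(int) * 10,
        hrdn_moving_std=np.zeros(n), valid=valid,
        excluded_fraction_mad=0.0, excluded_fraction_std=0.0)
    phase = np.array([phase_pattern[i % len(phase_pattern)]
                      for i in range(n)], dtype=object)
    rate = np.where(phase == "depressurization", -6.0,
                    np.where(phase == "repressurization", 6.0, 0.0))
    return SessionFeatures(subject_id=subject_id, session_id=session_id,
                           series=series, crm=crm, phase=phase,
                           ramp_rate=rate, baseline_end=60.0)


class TestAssemble:
    def test_phase_filter(self):
        data = assemble_dataset([_mock_session(1)], "all",
                                "depressurization")
        assert set(data["phase"]) == {"depressurization"}

    def test_hrdn_only_single_column(self):
        data = assemble_dataset([_mock_session(1)], "hrdn_only")
        assert FEATURE_SETS["hrdn_only"] == ["hrdn"]
        assert "hrdn" in data.columns and "sbp" not in data.columns

    def test_vital_signs_columns(self):
        assert FEATURE_SETS["vital_signs"] == ["ppi", "sbp", "hrv", "si",
                                               "dbp"]
        data = assemble_dataset([_mock_session(1)], "vital_signs")
        assert all(c in data.columns for c in FEATURE_SETS["vital_signs"])

    @pytest.mark.parametrize("kwargs", [
        {"feature_set": "bogus"},
        {"phase_selection": "sideways"},
        {"normalization": "zscore"},
    ])
    def test_unknown_names_rejected(self, kwargs):
        with pytest.raises(ValueError, match="unknown"):
            assemble_dataset([_mock_session(1)], **kwargs)


class TestFit:
    def test_ols_recovers_exact_line(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 2))
        y = 3.0 * X[:, 0] - 1.5 * X[:, 1] + 7.0
        model = fit_model(X, y, ModelConfig(model_kind="ols"))
        np.testing.assert_allclose(model.coef_, [3.0, -1.5], atol=1e-9)
        np.testing.assert_allclose(model.intercept_, 7.0, atol=1e-9)

    def test_gb_monotone_feature_high_r2(self):
        rng = np.random.default_rng(5)
        crm = rng.uniform(0, 100, size=500)
        X = (0.15 + 0.001 * crm).reshape(-1, 1)
        model = fit_model(X, crm, ModelConfig())
        pred = predict_crm(model, X)
        ss = 1 - np.sum((pred - crm) ** 2) / np.sum(
            (crm - crm.mean()) ** 2)
        assert ss > 0.99

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 3))
        y = rng.uniform(0, 100, size=100)
        p1 = predict_crm(fit_model(X, y, ModelConfig()), X)
        p2 = predict_crm(fit_model(X, y, ModelConfig()), X)
        np.testing.assert_array_equal(p1, p2)

    def test_constant_target_warns_and_predicts_constant(self):
        X = np.random.default_rng(9).normal(size=(50, 1))
        with pytest.warns(UserWarning, match="constant"):
            model = fit_model(X, np.full(50, 42.0), ModelConfig())
        np.testing.assert_allclose(model.predict(X), 42.0)

    def test_predictions_clipped(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(100, 1))
        y = 200.0 * X[:, 0]
        pred = predict_crm(fit_model(X, y, ModelConfig(model_kind="ols")),
                           X)
        assert pred.min() >= 0.0 and pred.max() <= 100.0


class TestSubjectwiseCV:
    def test_fold_sizes_for_13_subjects(self):
        folds = _partition_subjects(np.repeat(np.arange(13), 3), 5, seed=1)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [2, 2, 3, 3, 3]

    def test_folds_disjoint_and_cover(self):
        subjects = np.repeat(np.arange(1, 14), 5)
        folds = _partition_subjects(subjects, 5, seed=2)
        all_ids = np.concatenate(folds)
        assert len(all_ids) == len(set(all_ids)) == 13

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            _partition_subjects(np.array([1, 2, 3]), 5, seed=0)

    def test_cv_runs_and_no_leakage(self):
        sessions = [_mock_session(i, seed=i) for i in range(1, 9)]
        data = assemble_dataset(sessions, "hrdn_only")
        cv = subjectwise_cv(data, ["hrdn"], ModelConfig(), k=5, seed=0)
        held_out = [set(f["subjects"].tolist()) for f in cv.folds]
        for i, a in enumerate(held_out):
            for b in held_out[i + 1:]:
                assert not (a & b)
        assert set().union(*held_out) == set(range(1, 9))
        ref, est = cv.pooled()
        assert ref.size == len(data)
        assert est.min() >= 0.0 and est.max() <= 100.0


class TestImportance:
    def test_single_feature_importance_is_one(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(200, 1))
        model = fit_model(X, 50.0 + 10.0 * X[:, 0], ModelConfig())
        np.testing.assert_allclose(gini_importance(model), [1.0])

    def test_importances_normalized(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(300, 4))
        y = 20.0 * X[:, 2] + rng.normal(size=300)
        imp = gini_importance(fit_model(X, y, ModelConfig()))
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert (imp >= 0).all()
        assert imp.argmax() == 2

    def test_ols_has_no_gini_importance(self):
        X = np.random.default_rng(17).normal(size=(50, 2))
        model = fit_model(X, X[:, 0], ModelConfig(model_kind="ols"))
        with pytest.raises(TypeError):
            gini_importance(model)
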