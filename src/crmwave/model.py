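"""CRM regression: dataset assembly, OLS / GB-tree fits, subject-wise CV.

The compensatory reserve metric is estimated as a supervised regression of
the reference CRM (percent) on windowed waveform features.  Two model
families are supported: ordinary least squares, to probe linear structure,
and gradient-boosted regression trees (100 estimators, squared-error loss,
no bootstrap subsampling of rows) for nonlinear structure.  Tree depth and
learning rate are implementation defaults (3 and 0.1), not published
constants.

Because samples from the same individual are strongly correlated,
cross-validation folds are split **by subject**: a subject's windows never
appear in both the training and test side of a fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import LinearRegression

from .features import FEATURE_NAMES
from .postprocess import FeatureSeries, baseline_normalize

__all__ = [
    "FEATURE_SETS",
    "SessionFeatures",
    "ModelConfig",
    "CVResult",
    "assemble_dataset",
    "fit_model",
    "predict_crm",
    "subjectwise_cv",
    "gini_importance",
]

#: The four evaluated feature sets.
FEATURE_SETS = {
    "all": list(FEATURE_NAMES),
    "vital_signs": ["ppi", "sbp", "hrv", "si", "dbp"],
    "abp_waveform": ["ppi", "hrdn", "pp", "ipa"],
    "hrdn_only": ["hrdn"],
}

PHASE_SELECTIONS = ("full", "depressurization", "repressurization")


@dataclass
class SessionFeatures:
    """One session's windowed features plus the alignment metadata.

    ``crm`` is the reference CRM interpolated to the window times;
    ``phase`` the protocol phase at each window time; ``ramp_rate`` the
    signed mmHg/min rate for ramp windows (negative = depressurization,
    positive = repressurization, 0 = baseline/recovery).
    """

    subject_id: int
    session_id: int
    series: FeatureSeries
    crm: np.ndarray
    phase: np.ndarray
    ramp_rate: np.ndarray
    baseline_end: float


@dataclass(frozen=True)
class ModelConfig:
    """Regressor configuration.

    ``gb_tree`` uses 100 squared-error estimators without row subsampling;
    ``max_depth`` and ``learning_rate`` are tunable implementation choices.
    """

    model_kind: str = "gb_tree"
    n_estimators: int = 100
    max_depth: int = 3
    learning_rate: float = 0.1
    random_state: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in ("gb_tree", "ols"):
            raise ValueError(
                f"model_kind must be 'gb_tree' or 'ols', got "
                f"{self.model_kind!r}")


def assemble_dataset(
    sessions: Sequence[SessionFeatures],
    feature_set: str = "all",
    phase_selection: str = "full",
    normalization: str = "none",
) -> pd.DataFrame:
    """Stack valid windows of many sessions into a model-ready frame.

    Rows carry ``subject_id``, ``session_id``, ``phase``, ``ramp_rate``,
    ``window_time``, the selected feature columns, and the reference
    ``crm``.  Only windows where every selected feature is valid are kept.
    ``phase_selection`` restricts rows to the depressurization or
    repressurization phase; ``normalization="baseline"`` divides each
    feature by its mean over that session's baseline-phase windows.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(
            f"unknown feature_set {feature_set!r}; valid names: "
            f"{sorted(FEATURE_SETS)}")
    if phase_selection not in PHASE_SELECTIONS:
        raise ValueError(
            f"unknown phase_selection {phase_selection!r}; valid names: "
            f"{list(PHASE_SELECTIONS)}")
    if normalization not in ("none", "baseline"):
        raise ValueError(
            f"unknown normalization {normalization!r}; valid names: "
            f"['none', 'baseline']")
    if not sessions:
        raise ValueError("sessions must be nonempty")
    cols = FEATURE_SETS[feature_set]
    parts = []
    for sess in sessions:
        series = sess.series
        values = series.values
        if normalization == "baseline":
            values, _ = baseline_normalize(
                values, series.valid, series.window_times,
                sess.baseline_end)
        frame = values[cols].copy()
        frame["window_time"] = series.window_times
        frame["crm"] = sess.crm
        frame["phase"] = sess.phase
        frame["ramp_rate"] = sess.ramp_rate
        frame["subject_id"] = sess.subject_id
        frame["session_id"] = sess.session_id
        ok = series.valid[cols].all(axis=1).to_numpy()
        ok &= np.isfinite(frame[cols].to_numpy()).all(axis=1)
        if phase_selection == "depressurization":
            ok &= frame["phase"].to_numpy() == "depressurization"
        elif phase_selection == "repressurization":
            ok &= frame["phase"].to_numpy() == "repressurization"
        parts.append(frame.loc[ok])
    out = pd.concat(parts, ignore_index=True)
    meta = ["subject_id", "session_id", "phase", "ramp_rate", "window_time"]
    return out[meta + cols + ["crm"]]


def fit_model(X: np.ndarray, y: np.ndarray, config: ModelConfig):
    """Fit the configured regressor on a training matrix.

    Identical configuration and data give identical models.  A constant
    training target is legal (the model predicts that constant).
    """
    import warnings

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with at least one feature")
    if y.size and np.ptp(y) == 0.0:
        warnings.warn("training target is constant; the model will "
                      "predict that constant", stacklevel=2)
    if config.model_kind == "ols":
        model = LinearRegression()
    else:
        model = GradientBoostingRegressor(
            n_estimators=config.n_estimators,
            loss="squared_error",
            subsample=1.0,
            max_depth=config.max_depth,
            learning_rate=config.learning_rate,
            random_state=config.random_state,
        )
    model.fit(X, y)
    return model


def predict_crm(model, X: np.ndarray) -> np.ndarray:
    """Model predictions clipped to the physiologic CRM scale [0, 100]."""
    return np.clip(model.predict(np.asarray(X, dtype=float)), 0.0, 100.0)


def _partition_subjects(subjects: np.ndarray, k: int, seed: int
                        ) -> list[np.ndarray]:
    """Deal subjects round-robin into k folds after a seeded shuffle."""
    rng = np.random.default_rng(seed)
    ids = np.sort(np.unique(subjects))
    if ids.size < k:
        raise ValueError(
            f"need at least {k} subjects for {k}-fold subject-wise CV, "
            f"got {ids.size}")
    shuffled = rng.permutation(ids)
    return [shuffled[i::k] for i in range(k)]


@dataclass
class CVResult:
    """Per-fold predictions and importances from subject-wise CV."""

    folds: list = field(default_factory=list)  # dicts per fold
    feature_names: list = field(default_factory=list)

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """All held-out (reference, estimate) pairs pooled across folds."""
        ref = np.concatenate([f["y_true"] for f in self.folds])
        est = np.concatenate([f["y_pred"] for f in self.folds])
        return ref, est


def subjectwise_cv(
    data: pd.DataFrame,
    feature_cols: Sequence[str],
    config: ModelConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """K-fold cross-validation with folds split by subject.

    Subjects are shuffled deterministically by ``seed`` and dealt
    round-robin into ``k`` folds; each fold's model trains on the other
    folds' subjects and predicts the held-out subjects' windows.  The
    result stores per-fold held-out subjects, references, predictions, and
    (for tree models) Gini importances.
    """
    config = config or ModelConfig()
    subjects = data["subject_id"].to_numpy()
    folds = _partition_subjects(subjects, k, seed)
    cols = list(feature_cols)
    result = CVResult(feature_names=cols)
    X_all = data[cols].to_numpy(dtype=float)
    y_all = data["crm"].to_numpy(dtype=float)
    for fold_ids in folds:
        test = np.isin(subjects, fold_ids)
        model = fit_model(X_all[~test], y_all[~test], config)
        fold = {
            "subjects": fold_ids,
            "y_true": y_all[test],
            "y_pred": predict_crm(model, X_all[test]),
            "index": data.index[test].to_numpy(),
        }
        if config.model_kind == "gb_tree":
            fold["importances"] = gini_importance(model)
        result.folds.append(fold)
    return result


def gini_importance(model) -> np.ndarray:
    """Normalized impurity-decrease importances of a fitted tree ensemble.

    Each feature's importance is the normalized total decrease in the
    Friedman MSE split criterion attributable to splits on that feature;
    the vector is nonnegative and sums to 1.
    """
    if not hasattr(model, "feature_importances_"):
        raise TypeError(
            "Gini importance requires a fitted tree ensemble; "
            f"{type(model).__name__} does not expose feature_importances_")
    return np.asarray(model.feature_importances_, dtype=float)
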