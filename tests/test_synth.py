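"""Protocol generation, reference CRM, morphology maps, and waveform truth."""

import numpy as np
import pytest

import crmwave as cw
from conftest import clean_subject, flat_trace


class TestProtocol:
    def test_phase_durations_from_rates(self):
        # 60 mmHg at 6 mmHg/min is a 600-s ramp in each direction
        tr = cw.build_protocol(6.0, 6.0, 60.0, baseline_duration=300.0)
        down = tr.times[tr.phase_labels == "depressurization"]
        up = tr.times[tr.phase_labels == "repressurization"]
        assert down.max() - 300.0 == pytest.approx(600.0)
        assert up.max() - down.max() == pytest.approx(600.0)

    def test_full_tolerance_session(self):
        # a session ramped all the way to -100 mmHg is legal
        tr = cw.build_protocol(3.0, pmax=100.0)
        assert tr.pressure_magnitude.max() == pytest.approx(100.0)

    @pytest.mark.parametrize("kwargs", [
        {"down_rate": 6.0, "pmax": 0.0},
        {"down_rate": 0.0, "pmax": 60.0},
        {"down_rate": 6.0, "up_rate": -3.0, "pmax": 60.0},
        {"down_rate": 6.0, "pmax": 120.0},
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            cw.build_protocol(**kwargs)

    def test_trace_shape_invariants(self):
        tr = cw.build_protocol(9.0, 3.0, 45.0)
        p = tr.pressure_magnitude
        assert p.min() == 0.0 and p.max() == pytest.approx(45.0)
        assert np.all(p[tr.phase_labels == "baseline"] == 0.0)
        assert np.all(p[tr.phase_labels == "recovery"] == 0.0)
        # piecewise linear: interpolating the breakpoints reproduces it
        order = ["baseline", "depressurization", "repressurization",
                 "recovery"]
        seen = [ph for ph in order if np.any(tr.phase_labels == ph)]
        assert seen == order

    def test_depressurization_only_session(self):
        tr = cw.build_protocol(6.0, None, 60.0)
        assert not np.any(tr.phase_labels == "repressurization")
        assert tr.pressure_magnitude.max() == pytest.approx(60.0)


class TestReferenceCRM:
    def test_endpoints(self):
        assert cw.compute_reference_crm(np.array([0.0]), 60.0)[0] == 100.0
        assert cw.compute_reference_crm(np.array([60.0]), 60.0)[0] == 0.0

    def test_direct_substitution(self):
        assert cw.compute_reference_crm(np.array([45.0]), 60.0)[0] == (
            pytest.approx(25.0))

    def test_pressure_above_pmax_rejected(self):
        with pytest.raises(ValueError):
            cw.compute_reference_crm(np.array([61.0]), 60.0)

    def test_affine_in_pressure_on_random_protocols(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            pmax = rng.uniform(20.0, 100.0)
            tr = cw.build_protocol(rng.choice([3.0, 6.0, 9.0]),
                                   rng.choice([3.0, 6.0, 9.0]), pmax)
            crm = cw.compute_reference_crm(tr, pmax)
            assert np.all((crm >= 0.0) & (crm <= 100.0))
            expect = (1.0 - tr.pressure_magnitude / pmax) * 100.0
            np.testing.assert_allclose(crm, expect, rtol=0, atol=1e-12)
            ramp = tr.phase_labels == "depressurization"
            assert np.all(np.diff(crm[ramp]) <= 1e-12)
            rise = tr.phase_labels == "repressurization"
            assert np.all(np.diff(crm[rise]) >= -1e-12)


class TestMorphologyMap:
    def test_baseline_identity(self):
        subj = clean_subject(baseline_heart_rate=60.0)
        p = cw.crm_to_morphology(100.0, subj)
        assert p.period == pytest.approx(1.0)
        assert p.true_hrdn == pytest.approx(subj.baseline_hrdn)
        assert p.systolic_pressure == pytest.approx(subj.baseline_sbp)

    def test_monotone_in_crm(self):
        subj = clean_subject()
        lo, mid, hi = (cw.crm_to_morphology(c, subj) for c in (0, 50, 100))
        assert lo.true_hrdn < mid.true_hrdn < hi.true_hrdn
        assert lo.period < mid.period < hi.period
        assert (lo.systolic_pressure - lo.diastolic_pressure
                < hi.systolic_pressure - hi.diastolic_pressure)

    @pytest.mark.parametrize("crm", [-1.0, 100.5])
    def test_out_of_range_crm(self, crm):
        with pytest.raises(ValueError):
            cw.crm_to_morphology(crm, clean_subject())


class TestSynthesis:
    def test_beat_count_at_60bpm(self, steady_session):
        truth = steady_session["truth"]
        # 30 s at exactly 60 bpm
        assert len(truth) == 30
        np.testing.assert_allclose(np.diff(truth["t_onset"]), 1.0,
                                   atol=1e-9)

    def test_deterministic_given_seed(self):
        subj = clean_subject(noise_sd=1.0, jitter_sd=0.01,
                             hrdn_noise_sd=0.01, artifact_rate=2.0,
                             drift_amplitude=1.5)
        tr = flat_trace(20.0)
        rec1, truth1 = cw.synthesize_session(tr, subj, seed=11)
        rec2, truth2 = cw.synthesize_session(tr, subj, seed=11)
        assert np.array_equal(rec1.samples, rec2.samples)
        assert truth1.equals(truth2)

    def test_noiseless_beats_identical(self, steady_session):
        truth = steady_session["truth"]
        assert truth["hrdn"].nunique() == 1
        assert truth["sbp"].nunique() == 1

    def test_truth_hrdn_consistent_with_landmarks(self, ramp_session):
        truth = ramp_session["truth"]
        ok = truth["artifact"] == ""
        derived = truth.loc[ok, "t_notch"] - truth.loc[ok, "t_half_rise"]
        np.testing.assert_allclose(derived, truth.loc[ok, "hrdn"],
                                   atol=1.0 / 500.0)

    def test_waveform_amplitude_matches_truth(self, steady_session):
        rec = steady_session["recording"]
        subj = steady_session["subject"]
        assert rec.samples.max() == pytest.approx(subj.baseline_sbp,
                                                  abs=0.01)
        assert rec.samples.min() == pytest.approx(subj.baseline_dbp,
                                                  abs=0.01)


class TestCohortDesign:
    def test_four_sessions_per_subject(self):
        subjects = cw.draw_subjects(3, seed=0)
        specs = cw.cohort_sessions(subjects, seed=0)
        assert len(specs) == 12
        for subj in subjects:
            own = [s for s in specs if s.subject is subj]
            assert [s.session_id for s in own] == [1, 2, 3, 4]
            assert own[0].up_rate is None
            # first repressurization matches the depressurization rate,
            # the other two cover the remaining rates
            rates = {s.down_rate for s in own}
            assert rates == {own[0].down_rate}
            ups = sorted(s.up_rate for s in own[1:])
            assert sorted(set(ups)) == sorted({3.0, 6.0, 9.0})
            assert own[1].up_rate == own[1].down_rate
            # follow-up sessions stop at 70% of the tolerance pressure
            assert own[1].pmax == pytest.approx(0.7 * own[0].pmax)

    def test_subject_sampling_respects_invariants(self):
        for subj in cw.draw_subjects(20, seed=5):
            assert subj.baseline_sbp > subj.baseline_dbp > 0
            assert 0.15 < subj.baseline_hrdn < 0.45
            assert min(subj.hr_gain, subj.pp_gain, subj.hrdn_gain) >= 0
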