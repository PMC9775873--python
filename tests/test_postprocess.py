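"""MAD outlier rejection, window averaging, stability exclusion."""

import numpy as np
import pandas as pd
import pytest

from crmwave.postprocess import (baseline_normalize, hrdn_std_exclusion,
                                 mad_consistency_constant, moving_average,
                                 moving_std_centered, reject_outliers_mad,
                                 scaled_mad)


def brute_mad_mask(x, window=20, k=3.0):
    """Reference implementation of the documented rejection rule."""
    const = mad_consistency_constant()
    half = window // 2
    n = x.size
    keep = np.zeros(n, dtype=bool)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        win = x[i - h:i + h + 1]
        win = win[np.isfinite(win)]
        if not np.isfinite(x[i]) or win.size == 0:
            continue
        med = np.median(win)
        mad = const * np.median(np.abs(win - med))
        keep[i] = not (abs(x[i] - med) > k * mad)
    return keep


class TestScaledMAD:
    def test_consistency_constant(self):
        assert mad_consistency_constant() == pytest.approx(1.4826, abs=5e-5)

    def test_hand_example(self):
        # median 3, absolute deviations {2,1,0,1,2}, median deviation 1
        assert scaled_mad([1, 2, 3, 4, 5]) == pytest.approx(1.4826,
                                                            abs=5e-5)

    def test_constant_sequence(self):
        assert scaled_mad(np.full(9, 4.2)) == 0.0


class TestOutlierRejection:
    def test_constant_series_keeps_everything(self):
        keep = reject_outliers_mad(np.full(50, 3.3))
        assert keep.all()

    def test_single_spike_removed(self):
        rng = np.random.default_rng(2)
        x = 1.0 + 0.01 * rng.normal(size=40)
        x[17] = 10.0
        keep = reject_outliers_mad(x)
        assert not keep[17]
        assert keep.sum() == 39

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            n = rng.integers(5, 60)
            x = rng.normal(size=n)
            x[rng.random(n) < 0.1] *= 20.0
            x[rng.random(n) < 0.05] = np.nan
            np.testing.assert_array_equal(reject_outliers_mad(x),
                                          brute_mad_mask(x))

    def test_per_feature_independence(self):
        rng = np.random.default_rng(31)
        frame = pd.DataFrame({"a": rng.normal(size=40),
                              "b": np.ones(40)})
        frame.loc[5, "a"] = 50.0
        keep = reject_outliers_mad(frame)
        assert not keep.loc[5, "a"]
        assert keep["b"].all()

    def test_rejection_is_idempotent_on_retained(self):
        rng = np.random.default_rng(37)
        x = rng.normal(size=80)
        x[::13] += 25.0
        keep = reject_outliers_mad(x)
        again = reject_outliers_mad(np.where(keep, x, np.nan))
        assert again[keep].all()


class TestMovingAverage:
    def test_hop_is_two_seconds(self):
        t = np.arange(0.0, 100.0, 0.8)
        wt, mu, _ = moving_average(t, np.ones_like(t))
        np.testing.assert_allclose(np.diff(wt), 2.0)
        np.testing.assert_allclose(mu[np.isfinite(mu)], 1.0)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(41)
        t = np.sort(rng.uniform(0.0, 120.0, size=200))
        x = rng.normal(size=200)
        wt, mu, cnt = moving_average(t, x, min_beats=1)
        for j in rng.choice(wt.size, size=30, replace=False):
            sel = (t > wt[j] - 20.0) & (t <= wt[j])
            assert cnt[j] == sel.sum()
            if sel.any():
                assert mu[j] == pytest.approx(x[sel].mean(), rel=1e-9)

    def test_sparse_windows_invalid(self):
        t = np.array([1.0, 30.0, 61.0])
        _, mu, _ = moving_average(t, np.ones(3), min_beats=5)
        assert np.isnan(mu).all()

    def test_short_session_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.array([0.0, 5.0]), np.ones(2))


class TestCenteredStd:
    def test_constant_gives_zero(self):
        sd = moving_std_centered(np.full(60, 0.25))
        np.testing.assert_allclose(sd, 0.0)
        assert hrdn_std_exclusion(np.full(60, 0.25),
                                  threshold=0.0).all()

    def test_even_span_rejected(self):
        with pytest.raises(ValueError):
            moving_std_centered(np.ones(30), span=20)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(43)
        x = rng.normal(size=80)
        sd = moving_std_centered(x, span=21)
        for i in range(x.size):
            h = min(10, i, x.size - 1 - i)
            assert sd[i] == pytest.approx(x[i - h:i + h + 1].std(),
                                          rel=1e-9)

    def test_step_discontinuity_excluded(self):
        x = np.concatenate([np.full(40, 0.25), np.full(40, 0.35)])
        valid = hrdn_std_exclusion(x, threshold=0.02)
        # windows straddling the step are invalid, far windows are valid
        assert not valid[35:45].any()
        assert valid[:20].all() and valid[-20:].all()


class TestBaselineNormalize:
    def _series(self, values):
        frame = pd.DataFrame({"hrdn": values})
        valid = pd.DataFrame({"hrdn": np.ones(len(values), dtype=bool)})
        times = np.arange(len(values), dtype=float) * 2.0 + 20.0
        return frame, valid, times

    def test_identity_when_constant(self):
        frame, valid, times = self._series(np.full(40, 0.25))
        out, means = baseline_normalize(frame, valid, times, 50.0)
        np.testing.assert_allclose(out["hrdn"], 1.0)
        assert means["hrdn"] == pytest.approx(0.25)

    def test_double_baseline(self):
        values = np.full(40, 0.5)
        values[16:] = 1.0  # after baseline (ends at t=50 -> first 16)
        frame, valid, times = self._series(values)
        out, _ = baseline_normalize(frame, valid, times, 50.0)
        np.testing.assert_allclose(out["hrdn"][16:], 2.0)

    def test_missing_baseline_errors(self):
        frame, valid, times = self._series(np.full(10, 0.3))
        valid[:] = False
        with pytest.raises(ValueError, match="hrdn"):
            baseline_normalize(frame, valid, times, 50.0)
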