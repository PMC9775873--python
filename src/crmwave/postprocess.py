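"""Outlier rejection, window averaging, and stability-based exclusion.

Beat-level features are noisy: motion artifacts, mis-detected notches and
ectopic-looking beats produce isolated excursions.  Three stages clean them:

1. **Robust outlier rejection** — a moving median within a centred
   20-heartbeat window; points farther than 3 scaled median absolute
   deviations (MAD) from the window median are removed, per feature.  The
   scaled MAD is ``1.4826 * median(|A - median(A)|)``, the normal-consistent
   robust scale estimate.
2. **Local averaging** — a trailing 20-s moving-average window with 90%
   overlap (2-s hop) turns retained beat values into a windowed series.
3. **Stability exclusion** — the moving standard deviation of the HRDN
   window means, centred bilaterally across 21 adjacent windows, flags
   unstable stretches; windows whose HRDN std exceeds a threshold are
   excluded for *all* features.  The threshold is an empirically tuned
   configuration value (default 0.02 s), not a published constant.

Everything except the centred HRDN std is causal; a 20-s reporting delay
makes the whole chain causal for field deployment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES

__all__ = [
    "FeatureSeries",
    "mad_consistency_constant",
    "scaled_mad",
    "reject_outliers_mad",
    "moving_average",
    "moving_std_centered",
    "hrdn_std_exclusion",
    "baseline_normalize",
    "postprocess_features",
]


def mad_consistency_constant() -> float:
    """Scale factor making the MAD consistent for a normal distribution.

    Computed analytically as ``1 / Phi^-1(3/4)`` (approximately 1.4826),
    where ``Phi^-1`` is the standard normal quantile function.
    """
    return float(1.0 / stats.norm.ppf(0.75))


def scaled_mad(a, constant: float | None = None) -> float:
    """Scaled median absolute deviation of a sequence.

    ``constant * median(|a - median(a)|)`` with the normal-consistency
    constant by default; NaNs are ignored.
    """
    if constant is None:
        constant = mad_consistency_constant()
    a = np.asarray(a, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        return np.nan
    med = np.median(a)
    return constant * float(np.median(np.abs(a - med)))


def _centered_windows(n: int, half: int):
    """Yield (i, lo, hi) for symmetric centred windows, shrinking at edges."""
    for i in range(n):
        h = min(half, i, n - 1 - i)
        yield i, i - h, i + h + 1


def _rolling_centered(x: np.ndarray, half: int, fn) -> np.ndarray:
    """Apply ``fn`` over centred windows of half-width ``half``.

    Interior windows (full width ``2*half + 1``) are vectorized via a
    sliding-window view; edge windows shrink symmetrically.
    """
    n = x.size
    out = np.empty(n)
    width = 2 * half + 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if n >= width:
            view = np.lib.stride_tricks.sliding_window_view(x, width)
            out[half:n - half] = fn(view, axis=1)
        for i, lo, hi in _centered_windows(n, half):
            if half <= i < n - half:
                continue
            out[i] = fn(x[lo:hi])
    return out


def reject_outliers_mad(values, window: int = 20, k: float = 3.0,
                        constant: float | None = None):
    """Retention mask after moving-median / scaled-MAD outlier rejection.

    A value is removed iff its absolute deviation from the centred
    ``window``-beat moving median exceeds ``k`` scaled MADs of that window.
    Windows shrink symmetrically at the series edges; each feature column
    of a DataFrame is masked independently.  NaN inputs are never retained.
    Returns a boolean array/DataFrame of retained entries.
    """
    if constant is None:
        constant = mad_consistency_constant()
    if isinstance(values, pd.DataFrame):
        return values.apply(lambda col: pd.Series(
            reject_outliers_mad(col.to_numpy(), window, k, constant),
            index=values.index))
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return np.zeros(0, dtype=bool)
    half = window // 2
    med = _rolling_centered(x, half, np.nanmedian)
    dev = np.abs(x - med)
    # scaled MAD per window, computed on deviations from the window median
    n = x.size
    mad = np.empty(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        width = 2 * half + 1
        if n >= width:
            view = np.lib.stride_tricks.sliding_window_view(x, width)
            mad[half:n - half] = np.nanmedian(
                np.abs(view - med[half:n - half, None]), axis=1)
        for i, lo, hi in _centered_windows(n, half):
            if half <= i < n - half:
                continue
            mad[i] = np.nanmedian(np.abs(x[lo:hi] - med[i]))
    retained = ~(dev > k * constant * mad)
    retained &= np.isfinite(x)
    return retained


def moving_average(beat_times, values, retained=None, window: float = 20.0,
                   overlap: float = 0.9, min_beats: int = 5):
    """Trailing moving average of retained beat values.

    Windows are half-open intervals ``(t - window, t]`` whose right edges
    advance by ``hop = window * (1 - overlap)`` (2 s by default).  Returns
    ``(window_times, means, counts)`` where ``means``/``counts`` are
    DataFrames (or arrays for 1-D input); windows with fewer than
    ``min_beats`` retained beats have NaN means.
    """
    t = np.asarray(beat_times, dtype=float)
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    hop = window * (1.0 - overlap)
    squeeze = not isinstance(values, pd.DataFrame)
    frame = pd.DataFrame({"x": values}) if squeeze else values
    if retained is None:
        mask = frame.notna()
    else:
        mask = (pd.DataFrame({"x": retained}) if squeeze
                else pd.DataFrame(retained, columns=frame.columns))
        mask = mask.astype(bool) & frame.notna()
    if t.size == 0 or t[-1] < window:
        raise ValueError("session shorter than one averaging window")
    window_times = np.arange(window, t[-1] + 1e-9, hop)

    means = {}
    counts = {}
    order = np.argsort(t, kind="stable")
    ts = t[order]
    lo_idx = np.searchsorted(ts, window_times - window, side="right")
    hi_idx = np.searchsorted(ts, window_times, side="right")
    for col in frame.columns:
        x = frame[col].to_numpy(dtype=float)[order]
        m = mask[col].to_numpy()[order]
        xs = np.where(m, x, 0.0)
        cum = np.concatenate([[0.0], np.cumsum(xs)])
        cnt = np.concatenate([[0], np.cumsum(m.astype(int))])
        c = cnt[hi_idx] - cnt[lo_idx]
        s = cum[hi_idx] - cum[lo_idx]
        with np.errstate(invalid="ignore"):
            mu = np.where(c >= max(min_beats, 1), s / np.maximum(c, 1),
                          np.nan)
        means[col] = mu
        counts[col] = c
    means = pd.DataFrame(means)
    counts = pd.DataFrame(counts)
    if squeeze:
        return window_times, means["x"].to_numpy(), counts["x"].to_numpy()
    return window_times, means, counts


def moving_std_centered(x, span: int = 21) -> np.ndarray:
    """Moving standard deviation centred bilaterally across ``span`` windows.

    ``span`` must be odd; the window shrinks symmetrically at the series
    edges.  NaNs are ignored within each window (population std, ddof 0);
    all-NaN windows give NaN.
    """
    if span % 2 == 0:
        raise ValueError(f"span must be odd, got {span}")
    x = np.asarray(x, dtype=float)
    return _rolling_centered(x, span // 2, np.nanstd)


def hrdn_std_exclusion(hrdn_means, span: int = 21,
                       threshold: float = 0.02) -> np.ndarray:
    """Validity mask from the centred moving std of HRDN window means.

    A window is invalid iff the std of the HRDN means across the ``span``
    centred windows exceeds ``threshold`` seconds.  NaN stds (no valid
    HRDN in the span) are treated as invalid.
    """
    sd = moving_std_centered(hrdn_means, span)
    with np.errstate(invalid="ignore"):
        return np.isfinite(sd) & (sd <= threshold)


def baseline_normalize(values: pd.DataFrame, valid: pd.DataFrame,
                       window_times: np.ndarray, baseline_end: float
                       ) -> tuple[pd.DataFrame, dict]:
    """Divide each feature by its mean over the baseline-phase windows.

    Returns the dimensionless frame and the per-feature baseline means.
    Raises if a feature has no valid baseline window or a zero baseline
    mean, naming the feature.
    """
    in_baseline = np.asarray(window_times) <= baseline_end
    means = {}
    for col in values.columns:
        ok = in_baseline & valid[col].to_numpy() & np.isfinite(
            values[col].to_numpy())
        if not ok.any():
            raise ValueError(
                f"feature '{col}' has no valid baseline-phase window")
        mu = float(values[col].to_numpy()[ok].mean())
        if mu == 0.0:
            raise ValueError(f"feature '{col}' has zero baseline mean")
        means[col] = mu
    normalized = values / pd.Series(means)
    return normalized, means


@dataclass
class FeatureSeries:
    """Windowed feature series with validity bookkeeping.

    ``values`` holds the per-window feature means (one column per feature),
    ``valid`` the joint per-window, per-feature validity after the minimum
    beat count and the HRDN-stability exclusion, and the two
    ``excluded_fraction_*`` fields record how much data each rejection
    stage removed.
    """

    window_times: np.ndarray
    values: pd.DataFrame
    counts: pd.DataFrame
    hrdn_moving_std: np.ndarray
    valid: pd.DataFrame
    excluded_fraction_mad: float
    excluded_fraction_std: float
    baseline_means: dict = field(default_factory=dict)


def postprocess_features(
    beat_features: pd.DataFrame,
    mad_window: int = 20,
    mad_k: float = 3.0,
    window: float = 20.0,
    overlap: float = 0.9,
    min_beats: int = 5,
    hrdn_std_span: int = 21,
    hrdn_std_threshold: float = 0.02,
) -> FeatureSeries:
    """Run MAD rejection, moving averaging, and HRDN-stability exclusion."""
    feats = beat_features[FEATURE_NAMES]
    retained = reject_outliers_mad(feats, window=mad_window, k=mad_k)
    finite = feats.notna()
    n_finite = int(finite.to_numpy().sum())
    n_removed = int((finite & ~retained).to_numpy().sum())
    frac_mad = n_removed / n_finite if n_finite else 0.0

    window_times, means, counts = moving_average(
        beat_features["beat_time"], feats, retained,
        window=window, overlap=overlap, min_beats=min_beats)
    valid = means.notna()
    stable = hrdn_std_exclusion(means["hrdn"].to_numpy(),
                                span=hrdn_std_span,
                                threshold=hrdn_std_threshold)
    n_windows_ok = int(valid.to_numpy().any(axis=1).sum())
    n_std_removed = int((valid.to_numpy().any(axis=1) & ~stable).sum())
    frac_std = n_std_removed / n_windows_ok if n_windows_ok else 0.0
    valid = valid.copy()
    valid.loc[~stable, :] = False
    hrdn_sd = moving_std_centered(means["hrdn"].to_numpy(),
                                  span=hrdn_std_span)
    return FeatureSeries(window_times=window_times, values=means,
                         counts=counts, hrdn_moving_std=hrdn_sd,
                         valid=valid, excluded_fraction_mad=frac_mad,
                         excluded_fraction_std=frac_std)
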