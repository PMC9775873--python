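"""Per-beat pulse-morphology features.

Nine features are computed from the landmark times ``t_x`` and denoised
signal values ``W_x`` of each pulse (A = onset, B = systolic half-rise,
C = systolic peak, D = dicrotic notch, E = end of pulse, F = next systolic
peak):

======  ==========================  ============================
name    meaning                     formula
======  ==========================  ============================
ppi     peak-to-peak interval       t_F - t_C
hrv     heart-rate variability      RMSSD of PPI over 10 beats
hrdn    half-rise to dicrotic notch t_D - t_B
sbp     systolic blood pressure     W_C
dbp     diastolic blood pressure    W_E
pp      pulse pressure              W_C - W_A
pa      pulse area                  integral of W over [A, E]
ipa     inflection point area       integral over [D, E] / [A, D]
si      shock index                 60 / (PPI * SBP)
======  ==========================  ============================

Amplitudes and integrals are read from the denoised, unstandardized signal
(mmHg); integrals use the trapezoidal rule with linear interpolation at
fractional landmark times.  A feature whose landmark is missing is set to
NaN (invalid), never fabricated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_NAMES",
    "compute_beat_features",
    "compute_hrv",
    "rolling_rmssd",
    "compute_session_features",
]

FEATURE_NAMES = ["ppi", "hrv", "hrdn", "sbp", "dbp", "pp", "pa", "ipa", "si"]

#: Trailing window (in beats, including the current one) for the RMSSD
#: heart-rate-variability feature.
HRV_WINDOW_BEATS = 10


def _integrate(denoised: np.ndarray, fs: float, t_from: float, t_to: float
               ) -> float:
    """Trapezoidal integral of the signal over [t_from, t_to] seconds.

    Fractional endpoints are handled by linear interpolation between
    samples, so the result is exact for the piecewise-linear interpolant.
    """
    if not t_to > t_from:
        return np.nan
    i0 = int(np.ceil(t_from * fs - 1e-9))
    i1 = int(np.floor(t_to * fs + 1e-9))
    i1 = min(i1, denoised.size - 1)
    grid = np.arange(i0, i1 + 1) / fs
    vals = denoised[i0:i1 + 1]
    total = float(np.trapezoid(vals, grid)) if grid.size > 1 else 0.0
    v_from = float(np.interp(t_from, [max(i0 - 1, 0) / fs, i0 / fs],
                             [denoised[max(i0 - 1, 0)], denoised[i0]]))
    if i0 / fs > t_from:
        total += 0.5 * (v_from + vals[0]) * (i0 / fs - t_from)
    if t_to > i1 / fs:
        j = min(i1 + 1, denoised.size - 1)
        v_to = float(np.interp(t_to, [i1 / fs, max(j, i1 + 1) / fs],
                               [denoised[i1], denoised[j]]))
        total += 0.5 * (vals[-1] + v_to) * (t_to - i1 / fs)
    return total


def compute_beat_features(fid: pd.Series, denoised: np.ndarray, fs: float
                          ) -> dict:
    """Compute the per-beat features (all except HRV) for one pulse.

    ``fid`` is one row of the fiducial table.  Features whose landmarks are
    unresolved come back as NaN.  HRV needs the PPI history and is added by
    :func:`compute_session_features`.
    """
    out = {"beat_time": fid["t_A"]}
    ppi = fid["t_F"] - fid["t_C"]
    out["ppi"] = ppi
    out["sbp"] = fid["W_C"]
    out["dbp"] = fid["W_E"]
    out["pp"] = fid["W_C"] - fid["W_A"]
    out["si"] = 60.0 / (ppi * fid["W_C"]) if ppi > 0 else np.nan
    out["pa"] = (_integrate(denoised, fs, fid["t_A"], fid["t_E"])
                 if np.isfinite(fid["t_E"]) else np.nan)
    if fid.get("notch_found", False) and np.isfinite(fid["t_D"]):
        out["hrdn"] = fid["t_D"] - fid["t_B"]
        a_ad = _integrate(denoised, fs, fid["t_A"], fid["t_D"])
        a_de = _integrate(denoised, fs, fid["t_D"], fid["t_E"])
        out["ipa"] = a_de / a_ad if a_ad and a_ad > 0 else np.nan
    else:
        out["hrdn"] = np.nan
        out["ipa"] = np.nan
    return out


def compute_hrv(ppi_history) -> float:
    """RMSSD of a trailing PPI window: sqrt(mean(diff(PPI)**2)).

    Returns NaN until :data:`HRV_WINDOW_BEATS` intervals have accumulated
    (the window must be full and finite).
    """
    ppi = np.asarray(ppi_history, dtype=float)
    if ppi.size < HRV_WINDOW_BEATS or not np.all(np.isfinite(
            ppi[-HRV_WINDOW_BEATS:])):
        return np.nan
    window = ppi[-HRV_WINDOW_BEATS:]
    return float(np.sqrt(np.mean(np.diff(window) ** 2)))


def rolling_rmssd(ppi: pd.Series, window: int = HRV_WINDOW_BEATS
                  ) -> pd.Series:
    """Trailing RMSSD over ``window`` beats (current beat included)."""
    sq = ppi.diff() ** 2
    out = np.sqrt(sq.rolling(window - 1, min_periods=window - 1).mean())
    full = ppi.rolling(window, min_periods=window).count() >= window
    return out.where(full)


def compute_session_features(fiducials: pd.DataFrame, denoised: np.ndarray,
                             fs: float) -> pd.DataFrame:
    """Feature table for a whole record: one row per detected beat.

    Beats with ``exclusion_reason == "malformed_beat"`` contribute a row of
    NaNs (keeping beat indexing aligned); no-notch beats keep their
    amplitude/interval features but have NaN ``hrdn`` and ``ipa``.
    """
    rows = []
    for _, fid in fiducials.iterrows():
        if fid["exclusion_reason"] == "malformed_beat":
            row = dict.fromkeys(FEATURE_NAMES, np.nan)
            row["beat_time"] = fid["t_A"]
        else:
            row = compute_beat_features(fid, denoised, fs)
        rows.append(row)
    out = pd.DataFrame(rows, columns=["beat_time"] + FEATURE_NAMES)
    out["hrv"] = rolling_rmssd(out["ppi"])
    return out
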