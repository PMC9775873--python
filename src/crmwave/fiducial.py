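"""Beat segmentation and landmark detection on the denoised ABP pulse.

Each pulse is annotated with six landmarks: (A) start of pulse, (B) systolic
half-rise, (C) systolic peak, (D) dicrotic notch, (E) end of pulse, and (F)
systolic peak of the successive pulse.  Timing detection runs on the
standardized (trailing z-scored) signal and first derivative; landmark
*values* are read from the denoised, unstandardized signal so they keep
their mmHg units.

Dicrotic-notch selection: candidate notches are local maxima of the first
derivative after the systolic peak (the recovery upstroke out of the notch).
Among candidates falling within a credible time range — 15-40% of the
peak-to-peak interval, measured from the pulse onset — the maximally
prominent one is selected; pulses with no candidate in range are excluded
from analysis rather than given a fabricated notch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import ProcessedSignals

__all__ = ["segment_beats", "select_dicrotic_notch", "extract_fiducials"]

FIDUCIAL_COLUMNS = [
    "beat_index", "t_A", "t_B", "t_C", "t_D", "t_E", "t_F",
    "W_A", "W_C", "W_D", "W_E", "notch_found", "exclusion_reason",
]


def _systolic_peaks(signals: ProcessedSignals, min_ppi: float,
                    peak_prominence: float) -> np.ndarray:
    """Systolic peak indices from the standardized denoised signal."""
    distance = max(1, int(round(min_ppi * signals.fs)))
    peaks, _ = sps.find_peaks(signals.z_denoised, distance=distance,
                              prominence=peak_prominence)
    return peaks


def _feet(signals: ProcessedSignals, min_ppi: float, max_ppi: float,
          peak_prominence: float) -> tuple[np.ndarray, np.ndarray]:
    """Pulse-foot indices and foot (diastolic-minimum) values.

    The foot *time* is located by the intersecting-tangent rule: the
    tangent at the point of maximum upslope before each systolic peak is
    projected down to the level of the preceding diastolic minimum.  The
    lowpass filter rounds the sharp diastolic-to-upstroke corner, which
    biases a plain argmin into the flat diastolic tail; the tangent
    intersection stays pinned to the corner.  The foot *value* (used for
    the W_A / W_E amplitude readings) is the diastolic minimum itself.
    """
    den = signals.denoised
    d1 = signals.d1
    zpeaks = _systolic_peaks(signals, min_ppi, peak_prominence)
    feet = np.empty(zpeaks.size, dtype=int)
    foot_vals = np.empty(zpeaks.size)
    prev = int(zpeaks[0] - max_ppi * signals.fs) if zpeaks.size else 0
    for k, pk in enumerate(zpeaks):
        lo = max(prev, 0)
        i_min = lo + int(np.argmin(den[lo:pk + 1])) if pk > lo else lo
        onset = i_min
        if pk > i_min:
            i_ms = i_min + int(np.argmax(d1[i_min:pk + 1]))
            slope = d1[i_ms]
            if slope > 0:
                back = (den[i_ms] - den[i_min]) / slope * signals.fs
                onset = int(round(i_ms - back))
                onset = min(max(onset, i_min), pk - 1)
        feet[k] = onset
        foot_vals[k] = den[i_min]
        prev = pk
    return feet, foot_vals


def segment_beats(signals: ProcessedSignals, min_ppi: float = 0.3,
                  max_ppi: float = 2.0, peak_prominence: float = 1.0
                  ) -> np.ndarray:
    """Locate pulse onsets (points A).

    Systolic peaks are found on the standardized signal with a physiologic
    refractory distance; each onset is then placed at the foot of the
    upstroke preceding the peak by the intersecting-tangent rule (see
    :func:`_feet`).  A flat or too-short signal yields an empty array.
    """
    if signals.denoised.size < 2 * signals.fs:
        return np.empty(0, dtype=int)
    if _systolic_peaks(signals, min_ppi, peak_prominence).size == 0:
        return np.empty(0, dtype=int)
    feet, _ = _feet(signals, min_ppi, max_ppi, peak_prominence)
    return feet


def select_dicrotic_notch(candidates, t_A: float, ppi: float,
                          lo: float = 0.15, hi: float = 0.40):
    """Choose a dicrotic-notch candidate within the credible time range.

    ``candidates`` is a sequence of ``(time, prominence)`` pairs (times in
    seconds, absolute).  Candidates with ``(time - t_A) / ppi`` outside
    ``[lo, hi]`` are discarded; of the remainder the maximally prominent is
    returned (earliest wins a tie).  Returns the chosen pair or ``None``.
    """
    if ppi <= 0:
        raise ValueError(f"ppi must be positive, got {ppi}")
    in_range = [(t, p) for t, p in candidates
                if lo <= (t - t_A) / ppi <= hi]
    if not in_range:
        return None
    proms = np.asarray([p for _, p in in_range])
    return in_range[int(np.argmax(proms))]


def extract_fiducials(
    signals: ProcessedSignals,
    min_ppi: float = 0.3,
    max_ppi: float = 2.0,
    peak_prominence: float = 1.0,
    notch_range: tuple[float, float] = (0.15, 0.40),
    notch_min_prominence: float = 0.1,
) -> pd.DataFrame:
    """Detect all beats in a record and annotate the A-F landmarks.

    Returns one row per detected beat with landmark times (s), landmark
    values (mmHg, from the denoised signal), a ``notch_found`` flag, and an
    ``exclusion_reason`` of ``""`` (accepted), ``"no_notch_candidate"``, or
    ``"malformed_beat"``.  Malformed beats (no upstroke crossing, implausible
    interval, or the record's final beat with no successive peak) never
    raise; they are emitted with the reason set.
    """
    fs = signals.fs
    den = signals.denoised
    rows: list[dict] = []
    if (signals.denoised.size < 2 * fs
            or _systolic_peaks(signals, min_ppi, peak_prominence).size == 0):
        return pd.DataFrame(columns=FIDUCIAL_COLUMNS)
    onsets, foot_vals = _feet(signals, min_ppi, max_ppi, peak_prominence)
    # The standardized signal locates beats; the systolic peak itself is
    # re-read from the denoised pulse as the beat-window maximum (trailing
    # z-scoring can displace the apparent peak by tens of ms).
    n = den.size
    peaks = np.empty_like(onsets)
    for k, o_k in enumerate(onsets):
        end = (onsets[k + 1] if k + 1 < onsets.size
               else min(o_k + int(max_ppi * fs), n))
        end = max(end, o_k + 1)
        peaks[k] = o_k + int(np.argmax(den[o_k:end]))
    lo, hi = notch_range
    for k, (o_k, p_k) in enumerate(zip(onsets, peaks)):
        row = dict.fromkeys(FIDUCIAL_COLUMNS, np.nan)
        row.update(beat_index=k, notch_found=False, exclusion_reason="",
                   t_A=o_k / fs, t_C=p_k / fs, W_A=foot_vals[k],
                   W_C=den[p_k])
        if k + 1 >= peaks.size:
            row["exclusion_reason"] = "malformed_beat"
            rows.append(row)
            continue
        o_next, p_next = onsets[k + 1], peaks[k + 1]
        row.update(t_E=o_next / fs, t_F=p_next / fs,
                   W_E=foot_vals[k + 1])
        ppi = (p_next - p_k) / fs
        interval = (o_next - o_k) / fs
        if not (min_ppi <= interval <= max_ppi) or ppi <= 0:
            row["exclusion_reason"] = "malformed_beat"
            rows.append(row)
            continue

        # B: first upstroke crossing of the half-rise level, interpolated.
        mid = 0.5 * (row["W_A"] + row["W_C"])
        seg = den[o_k:p_k + 1]
        above = np.nonzero(seg >= mid)[0]
        if above.size == 0 or above[0] == 0:
            row["exclusion_reason"] = "malformed_beat"
            rows.append(row)
            continue
        j = above[0]
        frac = (mid - seg[j - 1]) / (seg[j] - seg[j - 1])
        row["t_B"] = (o_k + j - 1 + frac) / fs

        # D: candidate notches are first-derivative peaks after the
        # systolic peak (the recovery upstroke); each is refined to the
        # local pressure minimum immediately preceding it, then the
        # maximally prominent refined candidate inside the credible range
        # is selected.
        dseg = signals.z_d1[p_k:o_next + 1]
        cand_idx, props = sps.find_peaks(dseg,
                                         prominence=notch_min_prominence)
        cands = []
        seen = set()
        for ci, pr in zip(cand_idx, props["prominences"]):
            i = p_k + int(ci)
            while i > p_k and den[i - 1] <= den[i]:
                i -= 1
            if i not in seen:
                seen.add(i)
                cands.append((i / fs, pr))
        chosen = select_dicrotic_notch(cands, row["t_A"], ppi, lo, hi)
        if chosen is None:
            row["exclusion_reason"] = "no_notch_candidate"
            rows.append(row)
            continue
        i = int(round(chosen[0] * fs))
        row.update(t_D=i / fs, W_D=den[i], notch_found=True)
        rows.append(row)

    out = pd.DataFrame(rows, columns=FIDUCIAL_COLUMNS)
    out["notch_found"] = out["notch_found"].astype(bool)
    return out
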