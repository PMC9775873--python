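"""ABP pre-processing: zero-phase lowpass, derivatives, trailing z-score.

The raw 500 Hz ABP stream is smoothed with a 512th-order zero-phase FIR
lowpass (12 Hz cutoff), first and second derivatives are approximated as
finite differences of the denoised trace, and all three signals are z-scored
within a 2-s trailing window to detrend, remove baseline drift, and
standardize amplitude scaling for landmark detection.  Feature *amplitudes*
(mmHg) are always read from the denoised, unstandardized signal; only
landmark timing uses the standardized channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "ProcessedSignals",
    "design_lowpass",
    "lowpass_denoise",
    "finite_differences",
    "trailing_zscore",
    "preprocess",
]

#: Standard deviations below this (in signal units) are treated as a
#: degenerate (flatline) window and z-scored to 0.
DEGENERATE_SD = 1e-9


@dataclass
class ProcessedSignals:
    """Denoised ABP, its finite-difference derivatives, and z-scored copies.

    All six series share the input's length and time base.  ``valid_from``
    is the first index at which the 2-s trailing z-score window is complete.
    """

    fs: float
    denoised: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    z_denoised: np.ndarray
    z_d1: np.ndarray
    z_d2: np.ndarray
    valid_from: int


def design_lowpass(fs: float, order: int = 512, cutoff: float = 12.0
                   ) -> np.ndarray:
    """Design the linear-phase FIR lowpass kernel (``order + 1`` taps)."""
    if fs <= 2 * cutoff:
        raise ValueError(f"fs={fs} must exceed twice the cutoff {cutoff}")
    return sps.firwin(order + 1, cutoff, fs=fs)


def lowpass_denoise(raw: np.ndarray, fs: float, order: int = 512,
                    cutoff: float = 12.0) -> np.ndarray:
    """Zero-phase FIR lowpass via centred convolution of the symmetric kernel.

    A linear-phase (symmetric) FIR applied as a centred convolution is
    exactly zero phase, so a single overlap-add pass suffices.  The signal
    is reflect-padded by ``order`` samples at both ends; the output has the
    input's length.
    """
    x = np.asarray(raw, dtype=float)
    if x.size <= order:
        raise ValueError(
            f"signal of length {x.size} is shorter than the minimum "
            f"{order + 1} samples required by an order-{order} filter")
    taps = design_lowpass(fs, order=order, cutoff=cutoff)
    padded = np.concatenate([x[1:order + 1][::-1], x, x[-order - 1:-1][::-1]])
    full = sps.oaconvolve(padded, taps, mode="same")
    return full[order:order + x.size]


def finite_differences(denoised: np.ndarray, fs: float = 1.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """First (backward) and second (central) finite differences.

    ``d1[i] = (x[i] - x[i-1]) * fs`` and
    ``d2[i] = (x[i+1] - 2 x[i] + x[i-1]) * fs**2``; edge values are
    replicated from the nearest interior sample.  With ``fs=1`` the output
    is in per-sample units.
    """
    x = np.asarray(denoised, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples for finite differences")
    d1 = np.empty_like(x)
    d1[1:] = np.diff(x) * fs
    d1[0] = d1[1]
    d2 = np.empty_like(x)
    d2[1:-1] = (x[2:] - 2.0 * x[1:-1] + x[:-2]) * fs * fs
    d2[0] = d2[1]
    d2[-1] = d2[-2]
    return d1, d2


def trailing_zscore(x: np.ndarray, fs: float, window: float = 2.0
                    ) -> tuple[np.ndarray, int]:
    """Z-score each sample within the trailing ``window`` seconds.

    ``out[i] = (x[i] - mean) / sd`` over the window ending at (and
    including) sample ``i``.  Windows with sd below :data:`DEGENERATE_SD`
    (flatlines) produce 0.  Early samples use the shrinking partial window;
    the returned ``valid_from`` index marks the first complete window.
    """
    x = np.asarray(x, dtype=float)
    n_win = int(round(window * fs))
    if n_win < 2:
        raise ValueError("window must span at least 2 samples")
    s = pd.Series(x)
    mean = s.rolling(n_win, min_periods=1).mean().to_numpy()
    sd = s.rolling(n_win, min_periods=1).std(ddof=0).to_numpy()
    out = np.zeros_like(x)
    ok = sd > DEGENERATE_SD
    out[ok] = (x[ok] - mean[ok]) / sd[ok]
    return out, n_win - 1


def preprocess(raw: np.ndarray, fs: float, order: int = 512,
               cutoff: float = 12.0, z_window: float = 2.0
               ) -> ProcessedSignals:
    """Run the full pre-processing chain on a raw ABP stream."""
    denoised = lowpass_denoise(raw, fs, order=order, cutoff=cutoff)
    d1, d2 = finite_differences(denoised, fs)
    z_den, valid_from = trailing_zscore(denoised, fs, z_window)
    z_d1, _ = trailing_zscore(d1, fs, z_window)
    z_d2, _ = trailing_zscore(d2, fs, z_window)
    return ProcessedSignals(fs=fs, denoised=denoised, d1=d1, d2=d2,
                            z_denoised=z_den, z_d1=z_d1, z_d2=z_d2,
                            valid_from=valid_from)
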