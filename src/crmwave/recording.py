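"""Arterial blood pressure recordings and their plain-text round trip.

A recording is a single-channel, uniformly sampled ABP stream (mmHg) plus
session metadata.  The on-disk format is CSV with two columns,
``time_s`` and ``abp_mmhg``, preceded by ``#``-prefixed header lines that
carry the sample rate and metadata key/value pairs so the round trip is
lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ABPRecording", "write_recording_csv", "read_recording_csv"]


@dataclass
class ABPRecording:
    """A continuous ABP waveform sampled at a fixed rate.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    samples : ndarray
        Pressure samples in mmHg.
    metadata : dict
        Session metadata (subject id, session id, ramp rates, pmax, ...).
    """

    fs: float
    samples: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from session start."""
        return np.arange(self.samples.size) / self.fs


def write_recording_csv(path, rec: ABPRecording) -> None:
    """Write a recording as commented-header CSV (time_s, abp_mmhg)."""
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        for key, value in sorted(rec.metadata.items()):
            fh.write(f"# meta:{key}={value!r}\n")
        frame = pd.DataFrame({"time_s": rec.times, "abp_mmhg": rec.samples})
        frame.to_csv(fh, index=False, float_format="%.6f")


def read_recording_csv(path) -> ABPRecording:
    """Read a recording written by :func:`write_recording_csv`.

    Raises
    ------
    ValueError
        If the ``abp_mmhg`` column is absent or the header sample rate is
        inconsistent with the time column.
    """
    import ast

    fs = None
    metadata: dict = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if body.startswith("fs="):
                fs = float(ast.literal_eval(body[3:]))
            elif body.startswith("meta:"):
                key, _, raw = body[5:].partition("=")
                metadata[key] = ast.literal_eval(raw)
    frame = pd.read_csv(path, skiprows=skip)
    if "abp_mmhg" not in frame.columns:
        raise ValueError(
            f"{path}: missing required column 'abp_mmhg' "
            f"(found {list(frame.columns)})"
        )
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=' header line")
    if len(frame) > 1:
        dt = np.median(np.diff(frame["time_s"].to_numpy()))
        if abs(dt * fs - 1.0) > 1e-3:
            raise ValueError(
                f"{path}: header fs={fs} Hz inconsistent with time column "
                f"spacing {dt:.6g} s"
            )
    return ABPRecording(fs=fs, samples=frame["abp_mmhg"].to_numpy(),
                        metadata=metadata)
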