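"""Synthetic lower-body negative pressure (LBNP) sessions with truth tables.

LBNP redistributes blood toward the lower extremities by enclosing them in a
sub-atmospheric chamber, producing a noninvasive analogue of hemorrhage;
returning the chamber to ambient pressure emulates resuscitation.  The
compensatory reserve metric (CRM) runs from 100% (normovolemia) to 0%
(decompensation) and its reference value is defined directly from the chamber
pressure:  CRM(t) = (1 - P(t)/Pmax) * 100%, with P the magnitude of the
negative chamber pressure and Pmax the maximum pressure sustained in the
session.

This module generates

* ramped chamber-pressure protocols (baseline, linear depressurization at
  3/6/9 mmHg/min, optional linear repressurization, recovery),
* per-subject physiology (baseline heart rate, blood pressures, half-rise to
  dicrotic notch interval, response gains, noise levels), and
* beat-by-beat ABP waveforms whose morphology is modulated by the
  instantaneous reference CRM: as reserve is depleted, heart rate rises,
  pulse pressure falls, and the ejected-to-reflected wave delay (hence the
  true HRDN interval) shortens.

Every synthesized beat is logged in a truth table (landmark times, true
feature values, reference CRM) so that all downstream stages can be validated
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .recording import ABPRecording

__all__ = [
    "PHASES",
    "PressureTrace",
    "SubjectPhysiology",
    "PulseMorphParams",
    "SessionSpec",
    "build_protocol",
    "compute_reference_crm",
    "crm_to_morphology",
    "synthesize_session",
    "draw_subjects",
    "cohort_sessions",
    "simulate_cohort",
]

PHASES = ("baseline", "depressurization", "repressurization", "recovery")


@dataclass
class PressureTrace:
    """Magnitude of the negative chamber pressure over a session.

    ``pressure_magnitude`` is stored as a nonnegative magnitude in mmHg
    (0 = ambient); phase labels are one of :data:`PHASES` per sample.
    """

    times: np.ndarray
    pressure_magnitude: np.ndarray
    phase_labels: np.ndarray
    pmax: float

    def phase_at(self, t: np.ndarray) -> np.ndarray:
        """Phase label for arbitrary times (right edge owns the sample)."""
        idx = np.searchsorted(self.times, np.asarray(t), side="left")
        idx = np.clip(idx, 0, self.times.size - 1)
        return self.phase_labels[idx]

    def pressure_at(self, t: np.ndarray) -> np.ndarray:
        """Linearly interpolated pressure magnitude at arbitrary times."""
        return np.interp(np.asarray(t, dtype=float), self.times,
                         self.pressure_magnitude)


def build_protocol(
    down_rate: float,
    up_rate: float | None = None,
    pmax: float = 60.0,
    baseline_duration: float = 300.0,
    recovery_duration: float = 600.0,
    sample_interval: float = 1.0,
) -> PressureTrace:
    """Build a ramped LBNP chamber-pressure trace.

    The magnitude trace is 0 during baseline, rises linearly at ``down_rate``
    (mmHg/min) to ``pmax``, then — if ``up_rate`` is given — falls linearly
    back to 0 and stays at 0 for ``recovery_duration``.  Without ``up_rate``
    the chamber is released immediately at ``pmax`` (depressurization-only
    session) and the trace drops to 0 for the recovery period.

    The returned sample grid is the regular ``sample_interval`` grid merged
    with the exact phase breakpoints, so the trace is exactly piecewise
    linear and its maximum equals ``pmax``.
    """
    if down_rate <= 0:
        raise ValueError(f"down_rate must be positive, got {down_rate}")
    if up_rate is not None and up_rate <= 0:
        raise ValueError(f"up_rate must be positive, got {up_rate}")
    if not 0.0 < pmax <= 100.0:
        raise ValueError(f"pmax must lie in (0, 100] mmHg, got {pmax}")
    if sample_interval <= 0:
        raise ValueError("sample_interval must be positive")

    t_down_end = baseline_duration + pmax / down_rate * 60.0
    if up_rate is not None:
        t_up_end = t_down_end + pmax / up_rate * 60.0
    else:
        t_up_end = t_down_end
    t_total = t_up_end + recovery_duration

    breakpoints = [0.0, baseline_duration, t_down_end, t_up_end, t_total]
    grid = np.arange(0.0, t_total + 0.5 * sample_interval, sample_interval)
    times = np.unique(np.concatenate([grid, breakpoints]))
    times = times[times <= t_total + 1e-9]

    pressure = np.zeros_like(times)
    down = (times > baseline_duration) & (times <= t_down_end)
    pressure[down] = (times[down] - baseline_duration) * down_rate / 60.0
    if up_rate is not None:
        up = (times > t_down_end) & (times <= t_up_end)
        pressure[up] = pmax - (times[up] - t_down_end) * up_rate / 60.0
    pressure = np.clip(pressure, 0.0, pmax)

    labels = np.empty(times.size, dtype=object)
    labels[:] = "recovery"
    labels[times <= baseline_duration] = "baseline"
    labels[(times > baseline_duration) & (times <= t_down_end)] = (
        "depressurization")
    if up_rate is not None:
        labels[(times > t_down_end) & (times <= t_up_end)] = (
            "repressurization")
    return PressureTrace(times=times, pressure_magnitude=pressure,
                         phase_labels=labels, pmax=float(pmax))


def compute_reference_crm(pressure_magnitude, pmax: float) -> np.ndarray:
    """Reference CRM (percent) from pressure magnitude: (1 - P/Pmax) * 100.

    Accepts either a :class:`PressureTrace` or a bare magnitude array.
    100% at ambient pressure, 0% at ``pmax``; an error is raised if any
    pressure exceeds ``pmax`` (truth inconsistency).
    """
    if isinstance(pressure_magnitude, PressureTrace):
        pressure_magnitude = pressure_magnitude.pressure_magnitude
    p = np.asarray(pressure_magnitude, dtype=float)
    if pmax <= 0:
        raise ValueError(f"pmax must be positive, got {pmax}")
    if np.any(p < -1e-9) or np.any(p > pmax * (1 + 1e-9)):
        raise ValueError("pressure magnitudes must lie within [0, pmax]")
    return (1.0 - p / pmax) * 100.0


@dataclass(frozen=True)
class SubjectPhysiology:
    """Baseline physiology, CRM-response gains, and noise levels.

    The gains are dimensionless sensitivities applied to the CRM *deficit*
    d = (100 - CRM)/100:  heart rate rises by ``hr_gain * d`` (relative),
    pulse pressure falls by ``pp_gain * d``, and the true HRDN interval
    falls by ``hrdn_gain * d``.
    """

    subject_id: int
    baseline_heart_rate: float = 68.0     # bpm
    baseline_sbp: float = 120.0           # mmHg
    baseline_dbp: float = 75.0            # mmHg
    baseline_hrdn: float = 0.25           # s
    hr_gain: float = 0.45
    pp_gain: float = 0.25
    hrdn_gain: float = 0.45
    noise_sd: float = 1.0                 # waveform noise, mmHg
    jitter_sd: float = 0.010              # beat-to-beat period jitter, s
    hrdn_noise_sd: float = 0.010          # beat-level HRDN noise, s
    drift_amplitude: float = 1.5          # slow baseline drift, mmHg
    artifact_rate: float = 1.0            # artifact beats per minute
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.baseline_sbp > self.baseline_dbp > 0:
            raise ValueError("require baseline_sbp > baseline_dbp > 0")
        if not 0.15 < self.baseline_hrdn < 0.45:
            raise ValueError("baseline_hrdn must lie in (0.15, 0.45) s")
        if min(self.hr_gain, self.pp_gain, self.hrdn_gain) < 0:
            raise ValueError("response gains must be nonnegative")
        if self.pp_gain >= 1 or self.hrdn_gain >= 1:
            raise ValueError("pp_gain and hrdn_gain must be < 1")


@dataclass(frozen=True)
class PulseMorphParams:
    """Geometry of one arterial pulse.

    Times are seconds from the pulse onset (point A).  The pulse is built
    from four smooth segments: a quarter-sine systolic upstroke peaking at
    ``sys_peak_time``, a raised-cosine descent of the ejected wave into the
    dicrotic notch at ``notch_time``, a reflected-wave bump of width
    ``reflected_width`` and relative amplitude ``reflected_amp`` (fraction
    of pulse pressure), and an exponential diastolic decay with time
    constant ``decay_tau`` back to the diastolic level at the next onset.
    The upstroke is steepest at the foot (rapid ejection) and flat at the
    peak, so the systolic half-rise (point B) falls exactly at
    ``sys_peak_time / 3`` and the true HRDN interval is
    ``notch_time - sys_peak_time / 3``.
    """

    period: float
    sys_peak_time: float
    systolic_pressure: float
    diastolic_pressure: float
    notch_time: float
    notch_depth: float = 0.50
    reflected_amp: float = 0.20
    reflected_width: float = 0.10
    decay_tau: float = 0.35

    def __post_init__(self) -> None:
        if not (0.0 < self.sys_peak_time < self.notch_time
                < self.notch_time + self.reflected_width * self.period
                < self.period):
            raise ValueError(
                "require 0 < sys_peak_time < notch_time < notch_time + "
                "reflected bump width < period")
        if not 0.0 < self.notch_depth < 1.0:
            raise ValueError("notch_depth must lie in (0, 1)")
        if self.systolic_pressure <= self.diastolic_pressure:
            raise ValueError("systolic must exceed diastolic pressure")

    @property
    def true_hrdn(self) -> float:
        """Half-rise to dicrotic notch interval implied by the geometry."""
        return self.notch_time - self.sys_peak_time / 3.0


# Fraction of the period from onset to the systolic peak.  Keeping this
# proportional to the period keeps (t_D - t_A)/PPI inside the 15-40%
# credible band across the physiologic heart-rate range.
_SYS_PEAK_FRAC = 0.12


def crm_to_morphology(crm: float, subject: SubjectPhysiology
                      ) -> PulseMorphParams:
    """Map a CRM value (percent) to pulse morphology for one subject.

    Strictly monotone by construction: as CRM falls from 100 to 0 the beat
    period shortens (tachycardia), pulse pressure shrinks
    (reduced stroke volume), and the notch arrives earlier (vasoconstriction
    shortens the ejected-to-reflected delay).  At CRM = 100 the parameters
    equal the subject baseline.
    """
    if not 0.0 <= crm <= 100.0:
        raise ValueError(f"crm must lie in [0, 100], got {crm}")
    deficit = (100.0 - crm) / 100.0
    heart_rate = subject.baseline_heart_rate * (1.0 + subject.hr_gain * deficit)
    period = 60.0 / heart_rate
    pulse_pressure = (subject.baseline_sbp - subject.baseline_dbp) * (
        1.0 - subject.pp_gain * deficit)
    hrdn = subject.baseline_hrdn * (1.0 - subject.hrdn_gain * deficit)
    sys_peak_time = _SYS_PEAK_FRAC * period
    return PulseMorphParams(
        period=period,
        sys_peak_time=sys_peak_time,
        systolic_pressure=subject.baseline_dbp + pulse_pressure,
        diastolic_pressure=subject.baseline_dbp,
        notch_time=sys_peak_time / 3.0 + hrdn,
    )


def _beat_samples(params: PulseMorphParams, tau: np.ndarray,
                  artifact: str | None = None) -> np.ndarray:
    """Evaluate the pulse template at local times ``tau`` in [0, period).

    ``artifact`` is ``None`` for a normal beat, ``"no_notch"`` for a beat
    whose reflected wave is suppressed (monotone decay after the systolic
    peak, so no dicrotic notch exists), or ``"spike"`` for an
    amplitude-inflated beat.
    """
    T = params.period
    d = params.diastolic_pressure
    s = params.systolic_pressure
    if artifact == "spike":
        s = d + 1.6 * (s - d)
    t1 = params.sys_peak_time
    out = np.empty_like(tau)

    up = tau < t1
    out[up] = d + (s - d) * np.sin(0.5 * np.pi * tau[up] / t1)

    if artifact == "no_notch":
        # Monotone exponential descent from the systolic peak to the next
        # onset: no local minimum, so the notch detector must exclude it.
        rest = ~up
        tau_a = 0.30 * T
        e_end = np.exp(-(T - t1) / tau_a)
        frac = (np.exp(-(tau[rest] - t1) / tau_a) - e_end) / (1.0 - e_end)
        out[rest] = d + (s - d) * frac
        return out

    t_notch = params.notch_time
    w_notch = s - params.notch_depth * (s - d)
    t2 = t_notch + params.reflected_width * T
    w_refl = w_notch + params.reflected_amp * (s - d)
    tau_d = params.decay_tau * T

    desc = (tau >= t1) & (tau < t_notch)
    out[desc] = w_notch + (s - w_notch) * 0.5 * (
        1.0 + np.cos(np.pi * (tau[desc] - t1) / (t_notch - t1)))

    bump = (tau >= t_notch) & (tau < t2)
    out[bump] = w_notch + (w_refl - w_notch) * 0.5 * (
        1.0 - np.cos(np.pi * (tau[bump] - t_notch) / (t2 - t_notch)))

    tail = tau >= t2
    e_end = np.exp(-(T - t2) / tau_d)
    frac = (np.exp(-(tau[tail] - t2) / tau_d) - e_end) / (1.0 - e_end)
    out[tail] = d + (w_refl - d) * frac
    return out


def synthesize_session(
    trace: PressureTrace,
    subject: SubjectPhysiology,
    fs: float = 500.0,
    seed: int | None = None,
) -> tuple[ABPRecording, pd.DataFrame]:
    """Synthesize a full-session ABP waveform plus its truth table.

    Beats are placed back to back; each beat's morphology is evaluated at
    the reference CRM of its onset time, then perturbed by beat-level noise
    (period jitter, HRDN jitter), and occasional artifact beats are injected
    at ``subject.artifact_rate`` per minute.  Additive white measurement
    noise and a slow sinusoidal baseline drift are applied to the assembled
    waveform.  Identical seeds reproduce identical output bit for bit.

    Returns the recording and a truth table with one row per synthesized
    beat: landmark times (onset, half-rise, peak, notch, end), true values
    of the nine morphology features, the reference CRM at the beat onset,
    and the artifact label.
    """
    if fs <= 100:
        raise ValueError("fs must comfortably exceed the waveform bandwidth")
    if trace.times.size < 2:
        raise ValueError("pressure trace must be nonempty")
    rng = np.random.default_rng(subject.rng_seed if seed is None else seed)
    duration = float(trace.times[-1])
    n = int(round(duration * fs))
    crm_knots = compute_reference_crm(trace, trace.pmax)

    wave = np.full(n, subject.baseline_dbp, dtype=float)
    rows = []
    t = 0.0
    beat_index = 0
    while True:
        crm_b = float(np.interp(t, trace.times, crm_knots))
        base = crm_to_morphology(crm_b, subject)
        period = base.period + rng.normal(0.0, subject.jitter_sd)
        period = float(np.clip(period, 0.35, 1.9))
        if t + period > duration + 1e-9:
            break
        sys_peak = _SYS_PEAK_FRAC * period
        hrdn = base.true_hrdn + rng.normal(0.0, subject.hrdn_noise_sd)
        notch = sys_peak / 3.0 + hrdn
        notch = float(np.clip(notch, sys_peak + 0.02, 0.55 * period))
        artifact = None
        if rng.random() < subject.artifact_rate * period / 60.0:
            artifact = "no_notch" if rng.random() < 0.5 else "spike"
        params = replace(base, period=period, sys_peak_time=sys_peak,
                         notch_time=notch)

        i0 = int(np.ceil(t * fs - 1e-9))
        i1 = min(int(np.ceil((t + period) * fs - 1e-9)), n)
        tau = np.arange(i0, i1) / fs - t
        beat = _beat_samples(params, tau, artifact)
        wave[i0:i1] = beat

        sbp = params.systolic_pressure
        if artifact == "spike":
            sbp = params.diastolic_pressure + 1.6 * (
                sbp - params.diastolic_pressure)
        # Area truths from the noiseless sampled beat (trapezoid, same rule
        # as the feature extractor).
        tau0 = i0 / fs - t
        notch_off = (int(round((notch - tau0) * fs))
                     if artifact != "no_notch" else 0)
        pa = float(np.trapezoid(beat, dx=1.0 / fs))
        if artifact != "no_notch" and 0 < notch_off < beat.size:
            a_ad = float(np.trapezoid(beat[: notch_off + 1], dx=1.0 / fs))
            a_de = float(np.trapezoid(beat[notch_off:], dx=1.0 / fs))
            ipa = a_de / a_ad if a_ad > 0 else np.nan
        else:
            ipa = np.nan
        rows.append({
            "beat_index": beat_index,
            "t_onset": t,
            "t_half_rise": t + sys_peak / 3.0,
            "t_peak": t + sys_peak,
            "t_notch": (t + notch) if artifact != "no_notch" else np.nan,
            "t_end": t + period,
            "period": period,
            "crm": crm_b,
            "hrdn": hrdn if artifact != "no_notch" else np.nan,
            "sbp": sbp,
            "dbp": params.diastolic_pressure,
            "pp": sbp - params.diastolic_pressure,
            "pa": pa,
            "ipa": ipa,
            "artifact": artifact if artifact else "",
        })
        t += period
        beat_index += 1

    truth = pd.DataFrame(rows)
    if len(truth):
        ppi = truth["t_peak"].shift(-1) - truth["t_peak"]
        truth["ppi"] = ppi
        truth["si"] = 60.0 / (ppi * truth["sbp"])
        sq = ppi.diff() ** 2
        hrv = np.sqrt(sq.rolling(9, min_periods=9).mean())
        hrv[ppi.rolling(10, min_periods=10).count() < 10] = np.nan
        truth["hrv"] = hrv

    if subject.drift_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        wave += subject.drift_amplitude * np.sin(
            2.0 * np.pi * np.arange(n) / fs / 60.0 + phase)
    if subject.noise_sd > 0:
        wave += rng.normal(0.0, subject.noise_sd, size=n)

    rec = ABPRecording(fs=fs, samples=wave, metadata={
        "subject_id": subject.subject_id, "pmax": trace.pmax})
    return rec, truth


def draw_subjects(n_subjects: int = 13, seed: int = 0,
                  **overrides) -> list[SubjectPhysiology]:
    """Draw a cohort of subjects with inter-subject variability.

    Baseline parameters are sampled from uniform ranges representative of
    healthy adults; ``overrides`` replace any :class:`SubjectPhysiology`
    field for the whole cohort (e.g. ``noise_sd=0`` for noiseless tests).
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        dbp = rng.uniform(65.0, 85.0)
        fields = dict(
            subject_id=i + 1,
            baseline_heart_rate=rng.uniform(55.0, 66.0),
            baseline_dbp=dbp,
            baseline_sbp=dbp + rng.uniform(38.0, 55.0),
            baseline_hrdn=rng.uniform(0.235, 0.275),
            hr_gain=rng.uniform(0.35, 0.55),
            pp_gain=rng.uniform(0.15, 0.35),
            hrdn_gain=rng.uniform(0.38, 0.48),
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        fields.update(overrides)
        subjects.append(SubjectPhysiology(**fields))
    return subjects


@dataclass(frozen=True)
class SessionSpec:
    """One LBNP collection: who, which ramp rates, and to what pressure."""

    subject: SubjectPhysiology
    session_id: int
    down_rate: float
    up_rate: float | None
    pmax: float
    seed: int


def cohort_sessions(subjects: Sequence[SubjectPhysiology], seed: int = 0,
                    ) -> list[SessionSpec]:
    """Assign the four-session study design to each subject.

    Session 1 is depressurization-only, ramped at a randomly assigned
    3, 6, or 9 mmHg/min until the subject's tolerance pressure (drawn
    uniformly from 60-95 mmHg) is reached and then released.  Sessions 2-4
    depressurize at the same rate to 70% of that tolerance and repressurize
    at +3/+6/+9 mmHg/min: the first repressurization matches the
    depressurization rate, the other two are the remaining rates in random
    order.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for subject in subjects:
        down = float(rng.choice([3.0, 6.0, 9.0]))
        tolerance = float(rng.uniform(60.0, 95.0))
        up_rates = [down] + list(rng.permutation(
            [r for r in (3.0, 6.0, 9.0) if r != down]))
        session_seed = int(rng.integers(0, 2**31 - 1))
        specs.append(SessionSpec(subject, 1, down, None, tolerance,
                                 (session_seed + 1) % 2**31))
        for j, up in enumerate(up_rates, start=2):
            specs.append(SessionSpec(subject, j, down, float(up),
                                     0.7 * tolerance,
                                     (session_seed + j) % 2**31))
    return specs


def simulate_cohort(
    n_subjects: int = 13,
    seed: int = 0,
    fs: float = 500.0,
    **subject_overrides,
) -> Iterator[tuple[SessionSpec, PressureTrace, ABPRecording, pd.DataFrame]]:
    """Yield (spec, trace, recording, truth) for a full synthetic cohort.

    Sessions are generated lazily so a 52-session cohort never holds more
    than one waveform in memory.
    """
    subjects = draw_subjects(n_subjects, seed=seed, **subject_overrides)
    for spec in cohort_sessions(subjects, seed=seed + 1):
        trace = build_protocol(spec.down_rate, spec.up_rate, spec.pmax)
        rec, truth = synthesize_session(trace, spec.subject, fs=fs,
                                        seed=spec.seed)
        rec.metadata.update(session_id=spec.session_id,
                            down_rate=spec.down_rate,
                            up_rate=spec.up_rate)
        yield spec, trace, rec, truth
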