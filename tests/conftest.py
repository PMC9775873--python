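"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

import crmwave as cw


def flat_trace(duration: float, pmax: float = 60.0) -> cw.PressureTrace:
    """A zero-pressure (baseline-only) trace of the given duration."""
    times = np.array([0.0, duration])
    return cw.PressureTrace(
        times=times,
        pressure_magnitude=np.zeros(2),
        phase_labels=np.array(["baseline", "baseline"], dtype=object),
        pmax=pmax,
    )


def clean_subject(**overrides) -> cw.SubjectPhysiology:
    """A noiseless, artifact-free subject for deterministic truth checks."""
    fields = dict(subject_id=1, noise_sd=0.0, jitter_sd=0.0,
                  hrdn_noise_sd=0.0, drift_amplitude=0.0, artifact_rate=0.0)
    fields.update(overrides)
    return cw.SubjectPhysiology(**fields)


@pytest.fixture(scope="session")
def ramp_session():
    """Noiseless full-ramp session (baseline, down, up, recovery) with its
    preprocessed signals, fiducials, and beat features."""
    subject = clean_subject(baseline_heart_rate=62.0)
    trace = cw.build_protocol(6.0, 6.0, 60.0, baseline_duration=60.0,
                              recovery_duration=60.0)
    rec, truth = cw.synthesize_session(trace, subject, seed=7)
    signals = cw.preprocess(rec.samples, rec.fs)
    fiducials = cw.extract_fiducials(signals)
    beat_feats = cw.compute_session_features(fiducials, signals.denoised,
                                             rec.fs)
    return {
        "subject": subject, "trace": trace, "recording": rec,
        "truth": truth, "signals": signals, "fiducials": fiducials,
        "beat_features": beat_feats,
    }


@pytest.fixture(scope="session")
def steady_session():
    """Noiseless constant-CRM (100%) 30-s session at 60 bpm."""
    subject = clean_subject(baseline_heart_rate=60.0)
    trace = flat_trace(30.0)
    rec, truth = cw.synthesize_session(trace, subject, seed=3)
    signals = cw.preprocess(rec.samples, rec.fs)
    return {"subject": subject, "trace": trace, "recording": rec,
            "truth": truth, "signals": signals}
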