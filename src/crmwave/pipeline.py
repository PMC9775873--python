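"""End-to-end pipeline: simulate → preprocess → fiducials → features →
postprocess → model → evaluate.

`extract_session` turns one recording into a windowed
:class:`~crmwave.model.SessionFeatures`; `run_synthetic_cohort` generates a
whole cohort lazily and extracts every session; `run_experiment` assembles
the requested dataset variant, runs subject-wise cross-validation, and
returns the evaluation report.  `run_pipeline` ties it all together from a
:class:`~crmwave.config.PipelineConfig` and optionally writes every
intermediate table plus a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .evaluate import EvalReport, evaluate_cv
from .features import compute_session_features
from .fiducial import extract_fiducials
from .model import (ModelConfig, SessionFeatures, assemble_dataset,
                    subjectwise_cv)
from .postprocess import postprocess_features
from .preprocess import preprocess
from .recording import ABPRecording
from .synth import PressureTrace, compute_reference_crm, simulate_cohort

__all__ = ["extract_session", "run_synthetic_cohort", "run_experiment",
           "run_pipeline"]

log = logging.getLogger("crmwave")


def extract_session(rec: ABPRecording, trace: PressureTrace,
                    config: PipelineConfig | None = None,
                    subject_id: int = 0, session_id: int = 0,
                    down_rate: float | None = None,
                    up_rate: float | None = None) -> SessionFeatures:
    """Run the waveform-to-windowed-features chain on one session."""
    cfg = config or PipelineConfig()
    signals = preprocess(rec.samples, rec.fs, order=cfg.filter_order,
                         cutoff=cfg.filter_cutoff_hz,
                         z_window=cfg.zscore_window_s)
    fiducials = extract_fiducials(
        signals, min_ppi=cfg.min_ppi_s, max_ppi=cfg.max_ppi_s,
        peak_prominence=cfg.peak_prominence, notch_range=cfg.notch_range,
        notch_min_prominence=cfg.notch_min_prominence)
    beat_feats = compute_session_features(fiducials, signals.denoised,
                                          rec.fs)
    series = postprocess_features(
        beat_feats, mad_window=cfg.mad_window_beats, mad_k=cfg.mad_k,
        window=cfg.avg_window_s, overlap=cfg.avg_overlap,
        min_beats=cfg.min_beats_per_window,
        hrdn_std_span=cfg.hrdn_std_span,
        hrdn_std_threshold=cfg.hrdn_std_threshold_s)

    crm_knots = compute_reference_crm(trace, trace.pmax)
    crm = np.interp(series.window_times, trace.times, crm_knots)
    phase = trace.phase_at(series.window_times).astype(object)
    rate = np.zeros(series.window_times.size)
    if down_rate is not None:
        rate[phase == "depressurization"] = -down_rate
    if up_rate is not None:
        rate[phase == "repressurization"] = up_rate
    baseline_end = float(trace.times[trace.phase_labels == "baseline"].max())
    n_excl = int((fiducials["exclusion_reason"] == "no_notch_candidate")
                 .sum())
    log.info(
        "session %s/%s: %d beats, %d no-notch, MAD removed %.1f%%, "
        "HRDN-std removed %.1f%%", subject_id, session_id, len(fiducials),
        n_excl, 100 * series.excluded_fraction_mad,
        100 * series.excluded_fraction_std)
    return SessionFeatures(subject_id=subject_id, session_id=session_id,
                           series=series, crm=crm, phase=phase,
                           ramp_rate=rate, baseline_end=baseline_end)


def run_synthetic_cohort(config: PipelineConfig | None = None,
                         **subject_overrides) -> list[SessionFeatures]:
    """Simulate and extract a full synthetic cohort (lazily, per session)."""
    cfg = config or PipelineConfig()
    sessions = []
    for spec, trace, rec, _truth in simulate_cohort(
            cfg.n_subjects, seed=cfg.seed, fs=cfg.fs_hz,
            **subject_overrides):
        sessions.append(extract_session(
            rec, trace, cfg, subject_id=spec.subject.subject_id,
            session_id=spec.session_id, down_rate=spec.down_rate,
            up_rate=spec.up_rate))
    return sessions


def run_experiment(sessions, config: PipelineConfig | None = None,
                   feature_set: str | None = None,
                   phase_selection: str | None = None,
                   normalization: str | None = None
                   ) -> tuple[pd.DataFrame, EvalReport]:
    """Assemble a dataset variant, cross-validate, and evaluate it."""
    cfg = config or PipelineConfig()
    from .model import FEATURE_SETS
    fset = feature_set or cfg.feature_set
    data = assemble_dataset(sessions, feature_set=fset,
                            phase_selection=phase_selection
                            or cfg.phase_selection,
                            normalization=normalization or cfg.normalization)
    mc = ModelConfig(model_kind=cfg.model_kind,
                     n_estimators=cfg.n_estimators,
                     max_depth=cfg.max_depth,
                     learning_rate=cfg.learning_rate,
                     random_state=cfg.seed)
    cv = subjectwise_cv(data, FEATURE_SETS[fset], mc, k=cfg.cv_folds,
                        seed=cfg.seed)
    report = evaluate_cv(cv, data, thresholds=cfg.crm_thresholds)
    return data, report


def run_pipeline(config: PipelineConfig | None = None,
                 out_dir=None) -> EvalReport:
    """Full synthetic-cohort experiment; optionally write all tables.

    When ``out_dir`` is given, writes the assembled dataset, per-session
    windowed features, the evaluation report (JSON) and a manifest with the
    config, seed, and package version sufficient to reproduce the run.
    """
    cfg = config or PipelineConfig()
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    sessions = run_synthetic_cohort(cfg)
    data, report = run_experiment(sessions, cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        data.to_csv(out / "dataset.csv", index=False)
        windows = []
        for sess in sessions:
            frame = sess.series.values.copy()
            frame.insert(0, "window_time", sess.series.window_times)
            frame["hrdn_moving_std"] = sess.series.hrdn_moving_std
            frame["valid"] = sess.series.valid.all(axis=1).to_numpy()
            frame["crm"] = sess.crm
            frame["subject_id"] = sess.subject_id
            frame["session_id"] = sess.session_id
            windows.append(frame)
        pd.concat(windows, ignore_index=True).to_csv(
            out / "windowed_features.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        cfg_dict = cfg.to_dict()
        manifest = {
            "package_version": __version__,
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
            "seed": cfg.seed,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return report
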