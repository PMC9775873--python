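"""Accuracy, discrimination, and agreement metrics for CRM estimates.

* RMSE and R² between estimated and reference CRM.
* ROC AUC for binary classification of the reference at the clinically
  relevant thresholds CRM ≥ 70% (safe resuscitation endpoint), ≥ 40%
  (imminent-decompensation risk), and ≥ 5% (just above the decompensation
  point), scoring with the continuous estimate.  AUC is the Mann-Whitney
  rank statistic with ties counted half.
* Bland-Altman bias and ±1.96 SD limits of agreement of the paired
  differences (estimate − reference); the reference is the plotting
  x-coordinate since it is a gold standard, not an equally noisy method.
* Per-ramp-speed RMSE/R² distributions over sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvalReport",
    "regression_metrics",
    "roc_auc_at_threshold",
    "bland_altman",
    "per_speed_metrics",
    "evaluate_cv",
]

CRM_THRESHOLDS = (70.0, 40.0, 5.0)


def regression_metrics(est, ref) -> tuple[float, float]:
    """RMSE and coefficient of determination of estimates vs reference.

    ``rmse = sqrt(mean((est - ref)**2))`` and
    ``r2 = 1 - SS_res / SS_tot``.  R² is NaN for a constant reference.
    """
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.size < 2:
        raise ValueError("est and ref must be equal-length with >= 2 points")
    resid = est - ref
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0.0:
        return rmse, float("nan")
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return rmse, r2


def roc_auc_at_threshold(est, ref, threshold: float) -> float:
    """ROC AUC for detecting reference CRM >= threshold, scored by ``est``.

    Computed as the Mann-Whitney rank statistic: the probability that a
    random positive outranks a random negative, with ties counted 1/2.
    NaN if only one class is present.
    """
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    pos = ref >= threshold
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(est)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bland_altman(est, ref):
    """Bland-Altman agreement: bias, lower/upper limits, differences.

    ``bias = mean(est - ref)``; limits of agreement are
    ``bias ± 1.96 * sd(est - ref)`` (sample sd).
    """
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = est - ref
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, diff


def per_speed_metrics(session_frames: pd.DataFrame) -> pd.DataFrame:
    """Distribution of session-level RMSE/R² per signed ramp speed.

    ``session_frames`` must have columns ``session_key``, ``ramp_rate``
    (signed mmHg/min; depressurization negative, repressurization
    positive), ``crm`` and ``est``.  Session-level RMSE/R² are computed
    first over each session's windows at that rate, then summarized
    (median, quartiles, mean, sd, count) per rate.  Empty bins are absent.
    """
    rows = []
    ramp = session_frames[session_frames["ramp_rate"] != 0]
    for (rate, key), grp in ramp.groupby(["ramp_rate", "session_key"]):
        if len(grp) < 2:
            continue
        rmse, r2 = regression_metrics(grp["est"], grp["crm"])
        rows.append({"ramp_rate": rate, "session_key": key,
                     "rmse": rmse, "r2": r2})
    per_session = pd.DataFrame(rows)
    if per_session.empty:
        return pd.DataFrame(columns=["ramp_rate", "n_sessions", "rmse_median",
                                     "rmse_q1", "rmse_q3", "rmse_mean",
                                     "rmse_sd", "r2_mean"])
    out = []
    for rate, grp in per_session.groupby("ramp_rate"):
        out.append({
            "ramp_rate": rate,
            "n_sessions": len(grp),
            "rmse_median": grp["rmse"].median(),
            "rmse_q1": grp["rmse"].quantile(0.25),
            "rmse_q3": grp["rmse"].quantile(0.75),
            "rmse_mean": grp["rmse"].mean(),
            "rmse_sd": grp["rmse"].std(ddof=1) if len(grp) > 1 else 0.0,
            "r2_mean": grp["r2"].mean(),
        })
    return pd.DataFrame(out).sort_values("ramp_rate", ignore_index=True)


@dataclass
class EvalReport:
    """Cross-validated evaluation summary (fold mean ± sd conventions)."""

    rmse_mean: float
    rmse_sd: float
    r2_mean: float
    r2_sd: float
    auc_mean: dict
    auc_sd: dict
    ba_bias: float
    ba_loa_low: float
    ba_loa_high: float
    importances_mean: dict = field(default_factory=dict)
    per_speed: pd.DataFrame | None = None
    n_windows: int = 0

    def to_dict(self) -> dict:
        out = {
            "rmse_mean": self.rmse_mean, "rmse_sd": self.rmse_sd,
            "r2_mean": self.r2_mean, "r2_sd": self.r2_sd,
            "auc_mean": {str(k): v for k, v in self.auc_mean.items()},
            "auc_sd": {str(k): v for k, v in self.auc_sd.items()},
            "ba_bias": self.ba_bias,
            "ba_loa_low": self.ba_loa_low,
            "ba_loa_high": self.ba_loa_high,
            "importances_mean": self.importances_mean,
            "n_windows": self.n_windows,
        }
        if self.per_speed is not None:
            out["per_speed"] = self.per_speed.to_dict(orient="records")
        return out


def evaluate_cv(cv_result, data: pd.DataFrame | None = None,
                thresholds=CRM_THRESHOLDS) -> EvalReport:
    """Aggregate a :class:`~crmwave.model.CVResult` into an EvalReport.

    RMSE, R² and the threshold AUCs are computed per fold and reported as
    fold mean ± sd; Bland-Altman statistics are computed on the pooled
    held-out pairs.  If ``data`` (the assembled dataset) is given, the
    per-ramp-speed table is included.
    """
    per_fold = {"rmse": [], "r2": []}
    auc_fold = {t: [] for t in thresholds}
    imps = []
    for fold in cv_result.folds:
        rmse, r2 = regression_metrics(fold["y_pred"], fold["y_true"])
        per_fold["rmse"].append(rmse)
        per_fold["r2"].append(r2)
        for t in thresholds:
            auc_fold[t].append(
                roc_auc_at_threshold(fold["y_pred"], fold["y_true"], t))
        if "importances" in fold:
            imps.append(fold["importances"])
    ref, est = cv_result.pooled()
    bias, lo, hi, _ = bland_altman(est, ref)

    def _ms(vals):
        vals = np.asarray(vals, dtype=float)
        ok = np.isfinite(vals)
        if not ok.any():
            return float("nan"), float("nan")
        m = float(vals[ok].mean())
        s = float(vals[ok].std(ddof=1)) if ok.sum() > 1 else 0.0
        return m, s

    rmse_m, rmse_s = _ms(per_fold["rmse"])
    r2_m, r2_s = _ms(per_fold["r2"])
    auc_m, auc_s = {}, {}
    for t in thresholds:
        auc_m[t], auc_s[t] = _ms(auc_fold[t])
    importances = {}
    if imps:
        mean_imp = np.mean(np.vstack(imps), axis=0)
        importances = dict(zip(cv_result.feature_names, mean_imp.tolist()))

    per_speed = None
    if data is not None:
        frame = pd.DataFrame({
            "session_key": (data["subject_id"].astype(str) + ":"
                            + data["session_id"].astype(str)),
            "ramp_rate": data["ramp_rate"].to_numpy(),
            "crm": data["crm"].to_numpy(),
        })
        est_all = np.full(len(data), np.nan)
        for fold in cv_result.folds:
            est_all[np.searchsorted(data.index.to_numpy(),
                                    fold["index"])] = fold["y_pred"]
        frame["est"] = est_all
        per_speed = per_speed_metrics(frame.dropna(subset=["est"]))

    return EvalReport(rmse_mean=rmse_m, rmse_sd=rmse_s, r2_mean=r2_m,
                      r2_sd=r2_s, auc_mean=auc_m, auc_sd=auc_s,
                      ba_bias=bias, ba_loa_low=lo, ba_loa_high=hi,
                      importances_mean=importances, per_speed=per_speed,
                      n_windows=int(ref.size))
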