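"""Train the HRDN-only CRM model with subject-wise cross-validation.

Simulates a small cohort (5 subjects x 4 sessions), assembles the
full-procedure dataset, and cross-validates the gradient-boosted model
splitting folds by subject so no individual appears on both sides.
"""

import crmwave as cw
from crmwave.model import ModelConfig, subjectwise_cv

cfg = cw.PipelineConfig(n_subjects=5, seed=11)
sessions = cw.run_synthetic_cohort(cfg)
data = cw.assemble_dataset(sessions, feature_set="hrdn_only",
                           phase_selection="full", normalization="none")
print(f"dataset: {len(data)} windows from "
      f"{data['subject_id'].nunique()} subjects, "
      f"{data.groupby(['subject_id', 'session_id']).ngroups} sessions")

cv = subjectwise_cv(data, ["hrdn"], ModelConfig(random_state=11), k=5,
                    seed=11)
report = cw.evaluate_cv(cv, data)
print(f"RMSE : {report.rmse_mean:.1f} +/- {report.rmse_sd:.1f} % CRM")
print(f"R^2  : {report.r2_mean:.2f} +/- {report.r2_sd:.2f}")
for thr in (70.0, 40.0, 5.0):
    print(f"AUC at CRM >= {thr:>4.0f}% : {report.auc_mean[thr]:.3f}")
print(f"Bland-Altman bias {report.ba_bias:.1f}%, limits "
      f"[{report.ba_loa_low:.1f}, {report.ba_loa_high:.1f}]%")

# RMSE is in CRM percentage points on the 0-100% reserve scale; the AUCs
# measure how well the estimate separates windows above/below the three
# clinical thresholds (safe resuscitation endpoint, imminent-risk, and
# near-decompensation).
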