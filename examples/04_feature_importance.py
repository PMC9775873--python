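"""Which waveform features drive the CRM estimate?

Trains the all-features gradient-boosted model on a small synthetic
cohort and prints the cross-validated Gini importances (normalized
impurity decrease) and per-ramp-speed error table.
"""

import crmwave as cw
from crmwave.model import FEATURE_SETS, ModelConfig, subjectwise_cv

cfg = cw.PipelineConfig(n_subjects=5, seed=19)
sessions = cw.run_synthetic_cohort(cfg)
data = cw.assemble_dataset(sessions, feature_set="all")
cv = subjectwise_cv(data, FEATURE_SETS["all"], ModelConfig(random_state=19),
                    k=5, seed=19)
report = cw.evaluate_cv(cv, data)

print("mean Gini importance per feature:")
ranked = sorted(report.importances_mean.items(), key=lambda kv: -kv[1])
for name, imp in ranked:
    print(f"  {name:>5s} : {imp:.3f}  {'#' * int(60 * imp)}")

print("\nper-ramp-speed session RMSE (negative = simulated hemorrhage,"
      " positive = simulated resuscitation):")
cols = ["ramp_rate", "n_sessions", "rmse_median", "rmse_q1", "rmse_q3"]
print(report.per_speed[cols].round(2).to_string(index=False))

# In the generator, heart rate, pulse pressure and the ejected-to-
# reflected delay all co-vary with CRM, but HRDN carries the cleanest
# signal, mirroring its dominant importance.
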