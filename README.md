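# crmwave

Estimation of the **compensatory reserve metric (CRM)** from arterial
blood pressure (ABP) waveform morphology, for monitoring simulated
hemorrhage and resuscitation.

Traditional vital signs are late indicators of blood loss: the body
compensates (tachycardia, vasoconstriction) until shortly before
hemodynamic collapse. The CRM expresses the *remaining* compensatory
capacity on a 100%-to-0% scale — 100% is normovolemia, 0% is
decompensation. In the lower-body negative pressure (LBNP) model of
hemorrhage, a reference CRM is available directly from the chamber
pressure,

```
CRM(t) = (1 − P(t) / Pmax) · 100%
```

and the estimation task is to recover it from the ABP waveform alone.
The pipeline's key feature is **HRDN** — the time from the systolic
half-rise to the dicrotic notch, an approximate delay between the
ejected and reflected pressure waves — which shortens monotonically as
reserve is depleted.

The package provides, as a library plus narrative `examples/`:

* **`crmwave.synth`** — ramped LBNP protocols (±3/6/9 mmHg/min), cohort
  physiology, and 500 Hz ABP waveforms whose beat morphology is driven by
  the reference CRM, with a per-beat ground-truth table;
* **`crmwave.preprocess`** — 512th-order zero-phase 12 Hz FIR lowpass,
  finite-difference derivatives, 2-s trailing-window z-scoring;
* **`crmwave.fiducial`** — beat segmentation and the A–F pulse landmarks,
  including dicrotic-notch selection within a credible 15–40% band of the
  peak-to-peak interval;
* **`crmwave.features`** — nine per-beat morphology features (PPI, HRV,
  HRDN, SBP, DBP, PP, PA, IPA, SI);
* **`crmwave.postprocess`** — moving-median/scaled-MAD outlier rejection
  (20-beat windows, 3 MADs), 20-s / 90%-overlap moving averaging, and an
  HRDN-stability exclusion over 21 centred windows;
* **`crmwave.model`** — OLS and gradient-boosted-tree regression (100
  estimators, squared-error loss, no row subsampling) over four feature
  sets, with strictly subject-wise 5-fold cross-validation;
* **`crmwave.evaluate`** — RMSE, R², ROC AUC at the clinical CRM
  thresholds 70/40/5%, Bland–Altman agreement, Gini importances, and
  per-ramp-speed error tables.

A thin CLI (`crmwave simulate`, `crmwave run-all`) covers the two
shell-oriented workflows.

## Worked example

`python examples/03_train_and_validate.py` simulates five subjects with
four LBNP sessions each, extracts windowed features, and cross-validates
the HRDN-only gradient-boosted model with folds split by subject:

```
dataset: 22455 windows from 5 subjects, 20 sessions
RMSE : 10.1 +/- 2.7 % CRM
R^2  : 0.90 +/- 0.06
AUC at CRM >=   70% : 0.999
AUC at CRM >=   40% : 0.999
AUC at CRM >=    5% : 0.996
Bland-Altman bias -2.8%, limits [-22.4, 16.8]%
```

RMSE is in CRM percentage points on the 0–100% scale; R² measures how
much of the reference-CRM variance the estimate explains on held-out
subjects; the AUCs quantify discrimination of windows above/below the
safe-resuscitation (70%), imminent-risk (40%) and near-decompensation
(5%) thresholds; the Bland–Altman limits bound the typical
estimate-minus-reference disagreement. The other examples show session
simulation with ground truth, the waveform-to-features chain, and the
feature-importance / per-ramp-speed analysis.

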