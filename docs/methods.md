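# Methods

`crmwave` estimates the compensatory reserve metric (CRM) — a 100%-to-0%
scale of the physiological capacity remaining to compensate for central
blood-volume loss — from the morphology of the arterial blood pressure
(ABP) waveform. Because suitable human LBNP recordings are not freely
available, the package pairs the estimation pipeline with a synthetic-data
generator that produces full sessions with per-beat ground truth, so every
stage is testable end to end.

## Reference CRM and the simulated study design

Lower-body negative pressure (LBNP) redistributes blood into the lower
extremities, emulating hemorrhage; repressurization emulates resuscitation.
The reference CRM is defined from the chamber pressure alone:

    CRM(t) = (1 − P(t) / Pmax) · 100%

with `P(t)` the magnitude of the negative chamber pressure and `Pmax` the
maximum pressure sustained **in that session** (the per-session maximum of
the generated trace). Using the per-session maximum is a deliberate choice:
for ramp-up sessions that stop short of a subject's tolerance there is no
unambiguous alternative, and it guarantees the reference spans the full
0–100% range in every session.

The simulated design mirrors a two-day protocol: each subject contributes
one depressurization-only session ramped at −3, −6 or −9 mmHg/min until a
tolerance pressure (drawn uniformly from 60–95 mmHg) is reached and
released, and three sessions that ramp down at the same rate to 70% of that
tolerance and back up at +3/+6/+9 mmHg/min (the first repressurization rate
matches the down rate; the remaining two are assigned in random order).
Every session has a 5-min baseline and a 10-min recovery. A 13-subject
cohort therefore yields 52 sessions (13 depressurization, 39
repressurization).

## The pulse template

Each beat is a four-segment analytic template over one period `T`:

1. a quarter-sine systolic upstroke from the diastolic level to the
   systolic peak at `0.12 T` — steepest at the foot (rapid ejection), flat
   at the peak, placing the half-rise point exactly at one third of the
   peak time;
2. a raised-cosine descent of the ejected wave into the dicrotic notch
   (notch depth 50% of pulse pressure);
3. a raised-cosine reflected-wave bump (amplitude 20% of pulse pressure,
   width `0.10 T`); the notch is the unique local minimum between ejected
   and reflected components, and the bump's rising limb is the
   first-derivative peak the notch detector keys on;
4. an exponential diastolic decay back to the diastolic level at the next
   onset, so beats concatenate continuously.

The geometry makes the true half-rise and notch times exact, so the true
HRDN interval (half-rise to dicrotic notch, an approximate
ejected-to-reflected-wave delay) is a controllable parameter. The
segment proportions were chosen so that, across the sampled physiologic
range, the notch stays inside the 15–40% credible band of the peak-to-peak
interval and the ejected-wave descent stays long enough (≳75 ms) for the
12 Hz lowpass not to merge peak and notch.

CRM modulates the template through three strictly monotone maps applied to
the deficit `d = (100 − CRM)/100`: heart rate rises by `hr_gain · d`
(relative), pulse pressure falls by `pp_gain · d`, and the true HRDN falls
by `hrdn_gain · d`. At CRM = 100% the parameters equal the subject
baseline.

## Cohort variability and noise defaults

Per-subject baselines are drawn uniformly: heart rate 55–66 bpm (supine
rest; the upper bound keeps the baseline notch inside the credible band),
diastolic pressure 65–85 mmHg, pulse pressure 38–55 mmHg, baseline HRDN
235–275 ms, and gains `hr_gain` 0.35–0.55, `pp_gain` 0.15–0.35,
`hrdn_gain` 0.38–0.48. Noise defaults are beat-level HRDN jitter of 10 ms
SD, beat-period jitter of 10 ms SD, additive white waveform noise of
1 mmHg SD, a 1.5 mmHg slow sinusoidal baseline drift (period 60 s), and
artifact beats at 1 per minute (half with the reflected wave suppressed —
no notch exists — and half amplitude spikes at 1.6× pulse height). These
are the package's standing study conditions; tests and the acceptance
script run against them unchanged.

What the generator does **not** emulate: real Finapres noise spectra,
baroreflex and respiratory dynamics, waveform-shape classes beyond the
single template family, sensor artifacts other than the two injected
types, and any nonstationarity of subject physiology within a session.
Passing tests therefore demonstrate the pipeline's correctness and its
behavior under controlled, idealized variability — not clinical
performance on real recordings.

## Signal processing chain

* **Denoising** — 512th-order FIR lowpass, 12 Hz cutoff, applied with zero
  phase. Because a linear-phase FIR kernel is symmetric, a single centred
  convolution is exactly zero-phase; it is implemented by overlap-add with
  reflect padding of one filter order at each end (O(n log n), important at
  500 Hz × ~40 min sessions).
* **Derivatives** — backward first difference and central second
  difference of the denoised trace, scaled to physical units (mmHg/s,
  mmHg/s²), edges replicated. Landmark logic depends only on peaks and
  sign patterns, so the stencil choice is immaterial downstream.
* **Standardization** — z-score within a 2-s trailing window (population
  SD; windows with SD below 1e−9 output 0 to keep flatlines quiet). Beat
  *timing* detection runs on standardized channels; all mmHg amplitudes
  and areas are read from the denoised, unstandardized signal, since
  standardization destroys the units the amplitude features require.

### Landmarks

Systolic peak candidates come from peak-finding on the standardized signal
(refractory distance 0.3 s, prominence 1.0 in z units), then each peak is
re-read as the beat-window maximum of the denoised pulse. The pulse foot
(onset) is located by the intersecting-tangent rule — the tangent at the
point of maximum upslope projected down to the preceding diastolic
minimum — because a plain argmin drifts several ms into the flat diastolic
tail once the sharp corner has been smoothed by the 12 Hz filter; the foot
*amplitude* is still the diastolic minimum. The half-rise point is the
linearly interpolated crossing of the mean of onset and peak values.

Dicrotic-notch candidates are local maxima of the standardized first
derivative after the systolic peak (the recovery upstroke out of the
notch), each refined to the local pressure minimum immediately preceding
it. Candidates are filtered to a credible band — onset-to-notch time
between 15% and 40% of the current peak-to-peak interval — and the
maximally prominent survivor wins (earliest on ties). Beats with no
candidate in band are excluded rather than given a fabricated notch; the
final beat of a record is marked malformed (its PPI needs the next peak).

### Features

Nine per-beat features: PPI (peak-to-peak interval), HRV (RMSSD of PPI
over a trailing 10-beat window, invalid until the window fills), HRDN,
SBP (peak value), DBP (end-of-pulse value — the printed definition, kept
even though conventional DBP is the pre-upstroke minimum), PP (peak minus
onset value), PA (trapezoidal pulse area over onset-to-end), IPA (area
after the notch over area before it, integrated on the raw denoised
pressure without baseline subtraction), and SI (60 / (PPI · SBP)).
Features whose landmark is missing are NaN, never imputed.

### Cleaning and windowing

Per feature independently, values farther than 3 scaled MADs from a
centred 20-beat moving median are rejected; the scale constant is the
analytic normal-consistency value 1/Φ⁻¹(3/4) ≈ 1.4826, and centred
windows shrink symmetrically at the record edges. Retained values are
averaged in trailing 20-s windows with 90% overlap (2-s hop, half-open
intervals whose right edge owns the sample); windows with fewer than 5
retained beats are invalid. Finally the moving SD of the HRDN window
means, centred across 21 windows, gates *all* features: windows where it
exceeds a threshold are excluded together. The threshold is empirically
tuned in the original processing chain without a published value; the
default here is 0.02 s, exposed in configuration and flagged as an
implementation choice. Everything except this centred SD is causal, so a
20-s reporting delay makes the deployed chain causal.

## Modeling and evaluation

Windows with valid features become rows of (subject, session, phase,
signed ramp rate, features, reference CRM interpolated at the window's
right edge). Feature sets: all nine; vital signs (PPI, SBP, HRV, SI,
DBP); ABP-waveform (PPI, HRDN, PP, IPA); HRDN only. Dataset variants:
full procedure, depressurization-only, repressurization-only; optional
per-session baseline normalization divides each feature by its mean over
the baseline-phase windows.

Regressors: ordinary least squares, and gradient-boosted trees with 100
estimators, squared-error loss, and no row subsampling; tree depth 3 and
learning rate 0.1 are implementation defaults (not published constants),
exposed in `ModelConfig`. Predictions are clipped to [0, 100] at the
estimate layer, outside the regressor. Cross-validation splits folds by
subject (sorted, seeded shuffle, round-robin deal), so fold sizes for 13
subjects are {3,3,3,2,2} and no individual contributes to both sides of a
fold. RMSE, R² and the threshold AUCs (reference ≥ 70/40/5%, scored by
the continuous estimate, Mann-Whitney rank statistic with ties counted ½)
are reported as fold mean ± SD; Bland-Altman bias and ±1.96 SD limits use
the pooled held-out pairs with the reference as the x-coordinate; the
per-ramp-speed table computes session-level RMSE first and then
distribution statistics across sessions.

## Numerical choices and known limitations

* Integrals use the trapezoidal rule with linear interpolation at
  fractional landmark times.
* The 12 Hz lowpass slightly reshapes the sharp template: the systolic
  peak loses up to ~1 mmHg and the detected notch can shift a few ms.
  Interval features track the generator truth to within 10 ms for ≥99% of
  beats on noiseless sessions; the IPA ratio, whose numerator and
  denominator share the shifted notch boundary, is reproduced to within
  ~10% rather than the ~1% the pulse area achieves.
* The first beat of a record sits inside the filter's reflect-padded
  warm-up region and is usually distorted; truth-recovery statistics
  exclude the record edge.
* Problem sizes in the test suite were chosen to keep the full battery
  fast: the headline stand-in runs the complete 13-subject, 52-session
  cohort (~45 min of simulated waveform per session at 500 Hz), while
  property and oracle tests use seconds-long segments and thousands of
  small random instances.
* MAD rejection is per-feature; cross-feature coupling enters only at the
  HRDN-stability gate, where exclusion is collective. Whether the original
  chain couples features at the MAD stage is not documented; the
  per-feature reading is the less destructive one.
* Re-running the MAD rejector on its own retained output removes nothing
  further (verified by test); full pipeline idempotence in a stricter
  sense is not claimed, since window averaging is not a projection.
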