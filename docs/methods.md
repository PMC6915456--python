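# Methods

## Problem and pipeline

The target variable is a subjective 0–10 visual analog pain score
reported sparsely during a few-hour acute-care session, either through a
mobile app (continuous slider, so fractional values occur) or by nursing
staff (typically integers).  The predictors are eight wrist-wearable
channels sampled nominally at 1 Hz: HR (beats/min), RR interval (s),
GSR (kΩ), skin temperature (°C), Z-axis acceleration (g), Y/Z angular
velocity (deg/s) and a cumulative step counter.  The pipeline estimates
the score from the sensor data pooled across patients (between-subject
modelling); personalized per-patient models are out of scope.

Stages: timestamp alignment → moving-average denoising → per-channel
statistics → wrapper feature selection → cross-validated regression
(ridge, lasso, GPR, SVR) and 4-level classification (SVM), with a
categorized-SVR versus SVM comparison.

## Alignment

Pain timestamps carry only hour:minute, so each report is paired with
the 1-minute sensor segment starting at that minute.  When none exists,
the nearest segment within `tolerance_min` (default 10) is used,
justified by the slow drift of clinical pain over minutes.  Conventions
where the rule is underdetermined at minute resolution:

* "within 10 minutes" is implemented inclusively (lag ≤ 10); the
  open/closed distinction is a one-minute edge case and the bound is
  config-exposed;
* equidistant ties break toward the *earlier* segment, preferring
  physiology that precedes the report;
* `strategy="nearest"` is the default; `"earliest"` (first admissible
  segment) is available for sensitivity analysis;
* app and nurse reports follow the same rule, and reports never match
  segments from another session.

A channel enters a segment only if it supplies at least `min_coverage`
(default 0.8) of the nominal 60 samples/minute; minutes with no
qualifying channel are dropped.  Matching is conservative by
construction: matched + unmatched = total reports, every lag respects
the tolerance, and shrinking the tolerance can only shrink the matched
set (these are asserted as property tests).

## Features

Per channel and segment, after a centered moving-average filter with
edge truncation (window 5 samples ≈ 5 s at 1 Hz — long enough to damp
sample noise, short enough to keep minute-scale structure; the window is
config-exposed and must be odd so the window is symmetric):

| statistic | definition |
|---|---|
| mean | Σxᵢ/n |
| std | population standard deviation (1/n) |
| mean_derivative | mean of successive differences ÷ sampling interval (units/s) |
| rms | √(Σxᵢ²/n) |
| peak_to_peak | max − min |
| peak_to_rms | max\|xᵢ\| ÷ rms (undefined on an all-zero signal) |
| n_peaks | interior runs of equal values strictly above both neighbours (a plateau counts once, endpoints never) |
| power | Σ\|xᵢ\|²/n |

The population (1/n) form of the standard deviation was chosen for
consistency with the 1/n used by rms and power; rms² = power is then an
identity, asserted bit-exactly in tests via rms = √power.  STEPS is a
monotone counter on which most of these statistics degenerate, so it is
first-differenced to per-sample increments before filtering
(`steps_as_increments`, default on).  A statistic whose precondition
fails (too-short signal, all-zero peak_to_rms) is flagged missing, never
silently zeroed; rows containing missing entries are dropped — with a
logged count — before modelling.

## Models and selection

All features are standardized per training fold.  Defaults: ridge and
lasso strength α = 1.0; SVR ε = 0.1, C = 1.0; SVM C = 1.0; GPR
observation-noise nugget 0.1 on normalized targets.  Kernel methods use
an RBF kernel whose length scale is the median pairwise Euclidean
distance on the (standardized) training fold — a scale-free heuristic
that keeps SVR and SVM kernels identical for their comparison.
Hyperparameters are fixed per run rather than nested-tuned, matching
the single-model-per-family reporting style of the analysis.

The wrapper method scores candidate feature subsets by the k-fold
(default 10) out-of-fold RMSE of the chosen learner (SVR by default,
because selection is defined relative to a specific algorithm).
Forward selection starts from the empty, mean-only model and adds the
best feature until the improvement is ≤ `tol` (default 1e-4 on the RMSE
scale); backward elimination removes the feature whose removal most
improves — or least harms, within `tol` — the objective.  Candidate ties
break lexicographically by feature name so runs are deterministic.  The
greedy search is verified against an independently coded
exhaustive-greedy oracle on small instances.

Cross-validation pools rows from all sessions, the between-subject
design; a `group_by_session` mode (GroupKFold) is provided for
leakage-aware sensitivity analysis.  Out-of-fold evaluation is used for
every reported metric, including classification.

## Evaluation

RMSE is reported in pain-score units; its natural baseline is the
mean-only model, whose RMSE equals the population sd of the scores.
Pearson r measures the predicted/actual association.  For the ordinal
comparison, scores are categorized as none [0, 1), mild [1, 4),
moderate [4, 7), severe [7, 10] — the half-open fractional convention
anchored at the integer category bounds; the anchors themselves are not
configurable.  Classification is summarised by accuracy, per-class F1
(0 when precision + recall = 0) and the support-weighted F1;
zero-support classes are reported as absent and excluded from the
weighted average.  Regression predictions are clamped into [0, 10]
before categorization.  Residual tables carry the ± population-sd band
computed from the run's own scores.

## The synthetic cohort

The generator emulates the *structure* of an acute-pain day-hospital
cohort, not any patient's physiology:

* **Durations** ~ Normal(3.79 h, 2.23 h) truncated at 0.5 h; at 1 Hz a
  20-session cohort carries ~10⁵ samples per channel in total.
* **Latent pain p(t)**: piecewise constant with downward jumps at 2–4
  simulated medication times (treatment-driven relief, not a smooth
  ramp), total decrease ~ Normal(2.75, 2.34) clipped to [0, start].
  The severe-skewed 4-level weights (2/4/34/67) describe *reported*
  scores; since reports land at uniformly random times during a
  decreasing stay, the starting pain is the weighted draw shifted up by
  the expected incurred decrease at a random report time
  (mean_pain_decrease/2), capped at 10.  Pooled matched records then
  reproduce a severe-dominated distribution (~55–65 % severe) and a
  score sd near 2.
* **Channels** = baseline + coupling·p(t) + stationary AR(1) noise
  (coefficient 0.9 — correlated noise gives the moving-average filter
  realistic work).  Default couplings: HR +2 beats/min, GSR +5 kΩ per
  pain point, step rate −0.02 steps/s per pain point; all other
  channels uncoupled.  Baselines (HR 85 beats/min, RR 0.75 s, GSR
  200 kΩ, TEMP 33 °C) and noise sds are plausible wrist-wearable
  placeholders, not estimates of any dataset.
* **STEPS** is a cumulative Poisson counter with pain-dependent rate
  (base 0.25 steps/s): counter noise is intrinsic, so it has no
  additive-Gaussian term, and minutes with zero movement still occur
  (~5 % at pain 10), exercising the missing-feature path.
* **Reports**: 2 app scores (2 decimals) and 3–4 nurse scores (rounded
  to integers) drawn from p(t) at distinct random minutes; optional
  `nurse_bias` and `report_noise_sd` (both default 0) probe the
  assumption that app and nurse scores are interchangeable.
* **Determinism**: a cohort is a pure function of its `SimConfig`;
  session i is seeded `seed + i`.  The latent trajectory can be
  exported for parameter-recovery tests; the pipeline never reads it.

What the simulation does **not** emulate — and therefore what passing
tests do not show about clinical data: real waveform morphology,
HR/GSR confounders (movement, stress, medication side effects),
device dropout and artifacts, inter-patient baseline heterogeneity, and
any true pain–physiology transfer function.  The synthetic
pain–feature link is far cleaner than reality, so absolute metric
values (e.g. SVR r ≈ 0.97) characterise the pipeline, not achievable
clinical performance; the meaningful checks are structural (counts,
distributions), relational (all families beat the mean-only baseline;
categorized SVR ≥ SVM weighted F1 on skewed cohorts; selection recovers
the coupled channels) and exact (metric arithmetic against brute-force
oracles).

## Numerical and sizing choices

* Moving averages are computed as direct per-window means (segments are
  ≤ 60 samples), avoiding cumulative-sum cancellation error.
* CSV round trips are exact: files store full shortest-repr floats and
  are parsed with round-trip precision.
* Statistic/metric oracles in the test suite are plain-Python loop
  implementations compared at 1e-9 relative tolerance on 1000 random
  sequences (lengths 2–120).
* Simulation-based tests use 10-seed sweeps of 20-session cohorts
  (~107 matched records each), the cohort scale the generator's
  defaults describe; selection-oracle equivalence uses 20 random tables
  of ≤ 6 features, where exhaustive-greedy search is cheap.
* Degenerate inputs: empty feature sets fall back to the mean-only
  (or majority-class) model; constant-target folds fit an intercept
  with a warning; zero-variance inputs make Pearson r an error rather
  than a NaN.

## Known limitations

* Backward elimination over all 64 features evaluates ~2000 candidate
  subsets per run; it is supported (`--direction backward`) but the
  faster forward direction is the default everywhere.
* The 4-level categorization treats bins as exhaustive on [0, 10];
  out-of-range *actual* scores are rejected, only predictions are
  clamped.
* GPR uses a fixed median-heuristic length scale rather than marginal-
  likelihood optimization, trading a little accuracy for determinism.
* With fewer samples than folds the CV contract errors out by design;
  leave-one-out (k = n) is the supported extreme.
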