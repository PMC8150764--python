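# Methods

`wristpa` implements a laboratory-style pipeline for recognising physical
activity from raw wrist accelerometry: raw tri-axial signals (in g, at a
native 30/80/100 Hz rate) are cut into 60-s windows, summarised by 49
time/frequency features, and used to (1) recognise activity *type*
(sedentary / locomotion / lifestyle, as three one-vs-rest binary tasks),
(2) recognise activity *intensity* (low / light / moderate, likewise binary),
(3) recognise the 33 individual scripted activities (one multiclass task),
and (4) estimate energy expenditure in METs (regression). Models are trained
per age group (young [20, 50], middle (50, 70], old (70, 89] years) and on
the pooled cohort, with four learner families, and evaluated by
participant-grouped 5-fold nested cross-validation.

## Signal model of the synthetic cohort

The laboratory corpus this pipeline targets is not publicly deposited, so the
package ships a generator whose output exercises every stage. Each activity
is modelled per axis as

    a_i(t) = g_i + A_i · sin(2π f t + φ_i) + ε_i(t),   ε_i ~ N(0, σ²)

— a static gravity orientation `g` (unit vector), one dominant oscillation at
frequency `f` with per-axis amplitude `A` and a random phase per interval
(so windows within an activity are exchangeable but not identical), and
i.i.d. Gaussian sensor noise. The steady-state MET of each
participant-activity interval is drawn from Normal(met_mean, met_sd),
truncated below at 0.1 MET to exclude non-physical energy expenditure.

This is deliberately the *simplest* generator that makes the amplitude,
orientation and spectral features informative, and it is what the passing
pipeline tests demonstrate: that signal differences of this kind are
recovered end-to-end. It does not emulate gait harmonics, autocorrelated or
heteroscedastic noise, device-orientation drift, non-wear, or transitions
between activities, so test performance says nothing about accuracy on real
free-living data.

The default catalog holds the study's 33 activity names with package-chosen
parameters (the source's per-activity appendix is not available): sedentary
activities sit near 1–1.3 METs with millig amplitudes, locomotion at
1.5–2.3 Hz with the largest amplitudes, lifestyle activities in between, and
the four strength/stretching activities (typed `none`) at distinctive low
frequencies. MET means are placed at least ~4 sd from the intensity cutoffs
so that generated intervals are (with overwhelming probability, and
deterministically under the fixed test seeds) consistent with their
configured intensity class. Cohort defaults are 5 participants per age group,
100 Hz, 480 s per activity, one visit covering all activities ordered by
metabolic demand; ages are uniform in each group's bin.

## Features

Windows are anchored at each annotated interval's start; `floor(len/60 s)`
complete windows are taken and trailing data dropped, so no window straddles
an activity boundary. The 46 time-domain features are means, sds,
coefficients of variation, min/max, 25%/75% quantiles, third/fourth central
moments, skewness and kurtosis of the vector magnitude (VM) and the three
axes, plus the mean and sd of the angle `asin(x/VM)` (degrees). The three
frequency features use the DFT of the VM series with the DC bin excluded
(DC encodes gravity, not movement): `p625` is the fraction of spectral
modulus in 0.6–2.5 Hz (band edges inclusive), `df` the frequency of the
largest modulus, `fpdf` that bin's share of the total.

Numerical conventions, frozen for reproducibility where the feature
definitions are silent:

* sd uses the n−1 sample estimator; quantiles interpolate linearly between
  order statistics;
* third/fourth moments are population *central* moments;
  skewness = m3/m2^1.5, kurtosis = m4/m2² (non-excess); both 0 when
  m2 < 1e-24 g² (constant signal);
* CV = 100·sd/|mean|, reported as 0 with a logged warning when
  |mean| < 1e-6 g (per-axis means cross zero, and an unbounded CV would
  poison the feature table);
* angle is 0° at VM = 0; the asin argument is clamped to [−1, 1];
* dominant-frequency ties resolve to the lowest bin; an all-zero spectrum
  yields (0, 0, 0);
* signals at different native rates are never resampled — a 60-s window is
  1800, 4800 or 6000 samples.

All 46 time features are checked against an independent brute-force
re-implementation (different quantile/moment code paths) to 1e-9 relative
tolerance on randomly structured windows.

## VO2 and labels

Breath-by-breath VO2 (mL·min⁻¹·kg⁻¹) is smoothed by a centred 30-s running
average (partial windows at the edges); steady-state VO2 is the mean of the
smoothed series over a caller-chosen sub-interval — a reproducible stand-in
for manual plateau identification — and METs = VO2 / 3.5. Intensity cutoffs
(default low ≤ 1.5 < light ≤ 3.0 < moderate, upper bounds inclusive) and the
activity→type mapping are configuration, not constants: both are
user-overridable and the defaults must not be read as the source study's
(unavailable) assignments. Type recognition drops the four `none` activities,
leaving 29; the other tasks use all 33. Energy-expenditure rows are
restricted to participants with a valid-calorimetry flag.

## Learners

One contract (`modeling.fit`) covers four families: CART decision tree and
random forest (scikit-learn), gradient boosting (xgboost, `hist`, single
thread for determinism), and L1-penalised linear/logistic regression
("lasso"). Class imbalance is handled identically everywhere: per-row sample
weights equal to the row's inverse-frequency class weight N/(K·N_c). L1
models are fitted on standardised features since the 49 features span
several orders of magnitude; `C = 1/(n·alpha)` maps the lasso penalty onto
scikit-learn's logistic parameterisation, and coefficients are also exposed
in original units. Feature importance is impurity/gain importance for trees
and |standardised coefficient| for L1 models, always rescaled to sum to 1
(uniform if identically zero).

Hyperparameter grids (the study reports none) default to small conventional
ones — tree depth {3, 5, 10, ∞}; forest {100, 300} trees × {√p, p/3}
features/split; boosting depth {3, 6} × learning rate {0.1, 0.3} ×
{100, 300} rounds; a 50-point logarithmic lasso path anchored at the
training data's smallest all-zero penalty. `reduced_grids()` is the
desk-scale variant used by the test suite and the acceptance script, which
run the full 116-model grid on a 15-participant, 30 Hz, one-window-per-
activity cohort (495 windows) — small enough to complete in minutes while
leaving every structural property intact.

## Nested cross-validation

Participants are randomly assigned to 5 size-balanced outer folds; all of a
participant's windows share a fold, and the disjointness of outer train/test
participant sets is asserted on every fold of every run. For each outer
fold, an inner 4-fold grouped CV over the outer-training participants scores
each grid point (F1 for classification — positive-class F1 for binary tasks,
macro F1 for multiclass — and negative RMSE for regression; ties keep the
earlier grid point); the winner is refitted on the full outer-training set
with class weights recomputed there and evaluated on the held-out fold
(F1, AUC, balanced accuracy, accuracy; RMSE for regression). AUC is the
rank statistic P(score⁺ > score⁻) + ½P(tie), equal to the trapezoidal ROC
area. Metrics undefined on a fold (a class absent from the test fold) are
recorded as missing, logged, and excluded from the mean — never imputed.
Results report per-fold values, their mean ± sd, the confusion matrix summed
over outer folds, and fold-averaged importances; additionally the
hyperparameters with the best inner score can be refitted on all data
(`refit_final=True`) for deployment-style use.

The experiment grid enumerates 3 type targets × 4 algorithms × 4 strata
(48 models), 3 intensity targets × 4 × 4 (48), regression × 4 × 4 (16), and
the 33-class task with gradient boosting per stratum (4) — 116 models. The
"all" stratum trains on the pooled cohort. Empty strata are recorded as
skipped with a warning. Per-cell seeds derive from the run seed via a seed
sequence, so a rerun with the same seed is identical.

## Design choices and limitations

* The presentation follows the model/results pattern
  (`ActivityTaskModel.fit()` → `NestedCVResults.summary()`); the functional
  surface (`nested_cv`, `build_task_dataset`, ...) is equivalent.
* A 3-class `type_multiclass` dataset kind exists alongside the binary type
  tasks; it is used for separability diagnostics (macro F1 on a
  low-noise cohort).
* Exclusion reasons are evaluated in a fixed order (start/end times,
  sufficient data, demographics) so a participant failing several criteria
  is counted once, under the first reason.
* The raw CSV dialect is `timestamp,x,y,z` with seconds-from-start floats
  written at shortest round-trip precision; reading uses round-trip float
  parsing so read→write→read is byte-identical. ISO-8601 timestamps are
  accepted as a reader option. Declared rates are validated against the
  median sample spacing at 1% tolerance.
* Known limitations: no band-pass filtering, gravity removal,
  autocalibration or non-wear handling; no vigorous-intensity class; nested
  CV is not repeated, and no significance tests compare learners or strata.
  Performance numbers produced on synthetic cohorts characterise the
  pipeline's correctness and calibration, not expected accuracy on real
  populations.
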