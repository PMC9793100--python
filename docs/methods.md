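# Methods

This package re-implements, as a tested pipeline over synthetic cohorts, a
three-model analysis connecting psychosocial and stress-related factors
(PSFs), adverse pregnancy outcomes and pre-pregnancy risk factors
(together: APORFs), and single-cell immune features:

1. **Model 1** — a multitask neural network predicting 7 outcomes
   simultaneously from 79 questionnaire predictors, compared against
   single-task networks of identical architecture;
2. **Model 2** — a per-feature ridge regression screen predicting 534
   immune features from the PSFs plus a timepoint code, under grouped
   repeated cross-validation with FDR control;
3. **Model 3** — a single linear generator (the mean of all ridge fits)
   that imputes immune features for unmeasured patients, feeding the same
   multitask architecture to predict outcomes from generated immunology.

The study data themselves (questionnaire under copyright; no public
accession) are replaced by a generator that reproduces the structure the
stages assume; all quantitative claims made by the tests therefore concern
the machinery, not the original cohort.

## Synthetic cohort generator

**Outcome labels.** The six binary outcomes (hypertension, diabetes,
gestational diabetes, superimposed and severe preeclampsia, preterm birth)
are produced by a latent liability-threshold model: liabilities are
multivariate Gaussian with a configurable correlation matrix, and each
outcome's positives are the top-*k* liabilities, which hits the configured
case counts (defaults 18/11/29/6/13/17 in n = 200) exactly. The
"at least one APORF" union (default 52) is then enforced by moving labels
between patients nearest the thresholds, conserving every per-outcome
count. The published description gives only pairwise outcome correlations,
not a generative mechanism; the liability model is the simplest mechanism
with controllable binary co-occurrence, and the default correlation matrix
was calibrated once against the described network (a tight
hypertension/diabetes/superimposed-preeclampsia cluster; about half of all
outcome pairs moderately or strongly correlated after thresholding
attenuation).

**Continuous outcomes.** Gestational age (GA) at delivery is driven by the
preterm and severe-preeclampsia liabilities plus noise (so preterm cases
sit low); pre-pregnancy BMI by the hypertension/diabetes/gestational-
diabetes liabilities. GA at questionnaire completion is lognormal with
median 11 weeks (log-sd 0.30, truncated to 5–28 weeks), giving >95 % of
questionnaires before 21 weeks.

**PSFs.** 79 predictors in 15 correlated blocks (within-block Gaussian
correlation 0.6), discretised cyclically to yes/no, 8-point ordinal, and
continuous items — the instrument's scales — with 5 %
missing-completely-at-random entries to exercise the pairwise-complete
correlation paths. Outcome liabilities receive a PSF signal component: each
outcome's raw signal comes from two questionnaire blocks of its own, and the
per-outcome components are mixed through the Cholesky factor of the outcome
correlation matrix. Correlated outcomes therefore share predictor effects in
proportion to their correlation (the regime in which multitask learning can
transfer strength), and the liability correlation equals the configured
matrix regardless of the signal fraction. The default signal fraction is
0.25 of liability variance.

**Immune panel.** 14 patients (drawn from those without any adverse
outcome, matching the healthy measured sub-cohort) × 4 timepoints × 534
features; 40 features are linear in the scaled PSFs with Gaussian
coefficients (scale 0.6) plus a timepoint offset linear in the code and
noise (sd 0.5); the rest are standard normal noise. The planted
coefficients and the exact design matrix used are returned for recovery
tests. Note an identifiability constraint exploited by the tests: a
patient's four rows share one PSF vector, so the planted map is only
identifiable when the number of *patients* exceeds the number of
predictors — recovery tests use enlarged panels (120–150 patients), while
the 14-patient default matches the emulated study conditions under which
per-feature predictability is genuinely hard.

## Preprocessing

Patients whose preeclampsia status is entirely missing are removed
(283 → 200 on the packaged fixture). Configured text items are parsed to
numbers (bedtime → minutes after noon on a 24-hour wrap); then non-numeric
columns, columns with ≤1 unique non-missing value, and the named
age-inapplicable life-stress item are dropped, in that order (79 retained
on the fixture). Scaling divides each column by its sample standard
deviation (ddof = 1) computed on the fitting split only; columns are also
mean-centred (a deliberate addition — it makes ridge intercepts exact and
imputation neutral — switchable via `center=False`), and missing entries
are imputed by the fit-split mean. Binary items are {0, 1}; ordinals stay
integer.

## Outcome network

Pairwise Spearman correlations (average ranks, pairwise-complete deletion,
two-sided t-approximation p-values) over the 7 modelled outcomes. Edge
strength uses |rho| < 0.3 weak, 0.3–0.6 moderate, > 0.6 strong — the cited
strength taxonomy is a review of several scales without fixed cut points,
so these are configurable. Binary-binary pairs use the same statistic (a
phi-like reduction), with no special-casing.

## Multitask and single-task networks

Implemented directly in NumPy with manual backpropagation (the models are
small and full-batch, so explicit matrix code is fast and exactly seeded):
a linear feature embedding, two shared 150-unit hidden layers
(affine → batch-norm → ReLU), a per-task 150-unit module of the same form,
and per-task heads (sigmoid for binary, identity for numeric). Loss is the
sum of binary cross-entropies plus `mse_scale` × mean squared error for
numeric targets; numeric targets are standardised with training-fold
statistics and `mse_scale` defaults to 1, which realises "numeric targets
do not overpower the classification loss" without an extra tuning knob.
Training is full-batch Adam (learning rate 1e-3, the optimiser's customary
default; configurable) for at most 35 epochs, with early stopping at
patience 1 on the summed loss of an internal 20 % validation slice. The
validation slice is stratified on the joint binary-label pattern so that
rare outcomes' positives are proportionally represented — with 6–8
positives a validation slice without any of them cannot see the task
overfit, and overfitting the rare task is the dominant failure mode at
this sample size.

Evaluation: repeated stratified 5-fold cross-validation (stratified on the
any-outcome indicator; 20 repetitions by default), identical splits for
both model classes, held-out predictions pooled within each repetition and
summarised as one AUROC (binary) or Spearman rho (numeric) per task per
repetition. Model classes are compared with the Wilcoxon signed-rank test
paired by repetition (splits are shared; an unpaired rank-sum variant is
available) and annotated with the conventional star thresholds.

The single mild superimposed-preeclampsia case of the original cohort is a
preprocessing note rather than a pipeline stage here: the generator only
emits the severe/superimposed dichotomy.

## Stress-to-immune ridge screen

Each immune feature is predicted from the 79 PSFs plus the timepoint
integer (1–4). Outer loop: shuffled grouped 10-fold cross-validation over
patients (all four rows of a patient share a fold), repeated 50 times by
default; repetition *r* uses seed `seed + r` so any repetition is
individually reproducible. Within each outer training portion, a 5-fold
grouped grid search selects the penalty per feature from
(1, 0.1, 0.01, 0.001, 0.0001, 0) by validation MSE; alpha = 0 is
minimum-norm least squares, required because the design has more
predictors than training rows at the study scale. PSF columns are centred
and scaled to unit variance with training-portion statistics; the
timepoint column enters as raw integers (centring inside the ridge solver
only affects the intercept). Per repetition, Spearman rho and p are
computed per feature over all pooled held-out rows; rho and p are averaged
over repetitions and the mean p-values screened by Benjamini-Hochberg at
alpha 0.05. Averaging p-values over repetitions and then applying BH is
statistically unconventional (the mean of dependent p-values is not a
p-value); it is implemented as specified, with a median-combination
alternative behind `p_combine="median"`. Every fitted coefficient vector,
intercept, and training scaler is retained in the ensemble.

## Linear generator and Model 3

The generator is the unweighted elementwise mean of all repetition × fold
ridge fits — coefficients, intercepts, and training scaling parameters
alike ("all runs" read literally as every fitted slice). Generation is an
exact affine map with no noise injection, producing one matrix per
requested timepoint; the default is timepoint 1 (first trimester, when the
questionnaire was administered — which timepoint the imputed features
represent is otherwise unspecified). The 14 measured patients are excluded
from the downstream outcome models (hard error on overlap); the remaining
186 patients' generated features feed the same multitask/single-task
comparison as Model 1.

## Numerical choices and degenerate inputs

- Spearman with fewer than 3 complete pairs, or a constant input, yields a
  NaN marker rather than an exception; network edges over such pairs are
  categorised "undefined".
- K-means uses k-means++ with 10 restarts and a fixed seed; the raw signed
  correlation profiles are clustered while the *absolute* profiles are
  embedded (the two transformations are deliberately different and
  asserted in tests). Empty clusters trigger a re-seeded retry.
- t-SNE perplexity defaults to 10 (≈79 points), capped at (n−1)/3.
- Ridge ties in the alpha grid resolve to the first (largest) alpha.
- BH is the standard step-up via statsmodels.
- All randomness flows from integer seeds through `numpy` Generators;
  repeated runs are bitwise identical.

## What the synthetic data do and do not show

The generator reproduces: exact case counts and co-occurrence, block-
correlated mixed-type questionnaire items with missingness, a healthy
immune sub-cohort with patient-grouped repeated measures, and a
PSF → immune → outcome chain whose strength is controllable. It does not
reproduce: real item semantics (cluster labels are anonymous), non-MCAR
missingness, non-linear PSF-outcome relationships, CyTOF measurement
structure (arcsinh scales, compositional cell frequencies), or batch
effects. Passing tests therefore demonstrate that the machinery recovers
planted structure under the stated conditions — not that the original
biological claims replicate.

## Problem sizes used by tests and drivers

The default study conditions (200 patients, 79 PSFs, 534 immune features,
14 × 4 panel, 5-fold × 20 repetitions, 10-fold × 50 repetitions) are kept
for the stage-count checks. Statistical property checks run at sizes
chosen for identifiability and power rather than fidelity: recovery tests
use 120–150-patient panels and reduced repetition counts; calibration
suites use 20 seeds with 2 screen repetitions each; the end-to-end triad
uses a reduced immune feature count. Each test states its sizes inline.

## Known limitations

- The multitask-vs-single-task gain on rare outcomes is real but small at
  n = 200 with 6–8 positives, and sensitive to the early-stopping signal;
  the directional comparison is made at the 20-repetition median under the
  shared-effect, high-correlation regime.
- The 984 → 534 immune feature curation of the emulated study is
  undocumented; the generator simply emits 534 features.
- Which text items beyond "preferred bedtime" were parsed is unknown; the
  schema makes text parsing user-configurable.
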