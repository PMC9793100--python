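# stressmtl

Multitask modelling of adverse pregnancy outcomes from psychosocial
stress, with a stress-to-immune ridge screen and in-silico immune feature
generation.

## The problem

Adverse pregnancy outcomes (APOs) — gestational diabetes, severe and
superimposed preeclampsia, early gestational age (GA) at delivery — are
individually rare but strongly interrelated, both with each other and
with pre-pregnancy risk factors (RFs: diabetes, hypertension, BMI).
Psychosocial and stress-related factors (PSFs), captured cheaply by
questionnaire in the first trimester, are associated with these outcomes
and are modifiable. This package implements a pipeline for studying that
triad on tabular cohort data:

- **Model 1.** One shared-trunk neural network predicts all 7 APORFs
  simultaneously from 79 questionnaire predictors; multitask learning lets
  rare outcomes borrow statistical strength from correlated common ones.
  Performance is the per-repetition AUROC (binary tasks) or Spearman ρ
  (numeric tasks) over held-out predictions of repeated stratified 5-fold
  cross-validation, compared to single-task networks of identical
  architecture on identical splits with the Wilcoxon test.
- **Model 2.** For a small sub-cohort with mass-cytometry measurements at
  4 timepoints, ridge regression with an inner α grid search
  (α ∈ {1, 0.1, 0.01, 0.001, 0.0001, 0}) predicts each of 534 immune
  features from PSFs + a timepoint code under shuffled grouped 10-fold
  cross-validation (a patient's timepoints never straddle folds), repeated
  50×; per-feature mean Spearman p-values are screened by
  Benjamini–Hochberg FDR (α = 0.05).
- **Model 3.** The mean of all ridge fits defines a single linear
  generator ŷ = Wx + b that imputes immune features for the 186 patients
  without measurements; the Model-1 architecture then predicts APORFs from
  the generated immunology.

The original cohort data are restricted, so the package ships a
first-class synthetic generator (`stressmtl.synthetic`) that reproduces
the structure the stages assume — exact case counts
(18/11/29/6/13/17 in n = 200, 52 patients with ≥1 APORF) via a latent
liability-threshold model, 79 block-correlated mixed-type questionnaire
items, and an immune panel with planted linear PSF signal — so every
stage is testable against known ground truth. See `docs/methods.md`.

## Worked example

```sh
python analysis/01_simulate_cohort.py 1
```

```
cohort: 200 patients
hypertension            18
diabetes                11
gestational_diabetes    29
superimposed_pree        6
severe_pree             13
preterm                 17
any adverse outcome / risk factor: 52
median GA at questionnaire: 11.2 weeks (99.0% before 21 weeks)
immune panel: 14 patients x 4 timepoints, 534 features (40 with planted stress signal)
```

The per-outcome positive counts and the 52-patient union match the
configured composition exactly (they are enforced by thresholding
correlated liabilities and minimal label moves), and the questionnaire-
timing distribution has its median in week 11 with nearly all
questionnaires before 21 weeks.

```sh
python analysis/02_outcome_network.py 1
```

```
                      hypertension  diabetes  gestational_diabetes  superimposed_pree  severe_pree  ga_delivery   bmi
hypertension                  1.00      0.54                  0.32               0.56         0.06        -0.19  0.47
diabetes                      0.54      1.00                  0.40               0.47         0.11        -0.20  0.37
gestational_diabetes          0.32      0.40                  1.00               0.09         0.12        -0.36  0.47
superimposed_pree             0.56      0.47                  0.09               1.00        -0.05        -0.15  0.27
severe_pree                   0.06      0.11                  0.12              -0.05         1.00        -0.39  0.24
ga_delivery                  -0.19     -0.20                 -0.36              -0.15        -0.39         1.00 -0.39
bmi                           0.47      0.37                  0.47               0.27         0.24        -0.39  1.00

21 edges: 0 strong, 11 moderate (52% moderate-or-strong)
```

Hypertension, diabetes and superimposed preeclampsia form the tight
cluster; GA at delivery anchors the prematurity axis; about half of all
outcome pairs are moderately or strongly correlated — the premise for
modelling them jointly. The remaining drivers
(`03_multitask_vs_singletask.py`, `04_stressor_clusters.py`,
`05_stress_to_immune.py`, `06_generated_immune_aporfs.py`) run Models
1–3 and the stressor-category analysis, writing tables under `results/`.

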