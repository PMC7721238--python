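# Methods

## Problem and model

`scdprog` predicts which individuals with subjective cognitive decline (SCD)
— self-reported memory worsening with objectively normal neuropsychology —
will progress to amnestic mild cognitive impairment (MCI) years later, from
baseline data only. The classification target is binary: progressive SCD
(pSCD, label 1) versus stable SCD (sSCD, label 0), in a small, imbalanced
cohort (canonically 76 subjects, 24 progressive).

The feature space combines 25 clinical/demographic variables with 198
structural-MRI morphometric features from a Desikan–Killiany parcellation:
46 global segmentation volumes (mm³, unnormalized), 68 mean cortical
thicknesses (mm, unnormalized), 68 gyral white-matter volumes divided by
the subject's total WM volume, and 16 subcortical volumes divided by the
subject's total subcortical volume. Normalizing the two volume blocks
within-subject removes global-atrophy confounds; each normalized block sums
to exactly 1 per subject.

The pipeline has three stages inside a nested leave-one-out cross-validation
(LOOCV):

1. **Ensemble ReliefF ranking.** ReliefF weights a feature by the average
   difference of its (range-normalized) value between each subject and its k
   nearest same-class neighbors (hits, penalized) versus its k nearest
   opposite-class neighbors (misses, rewarded). Because k is not known a
   priori, weights are computed for k = 1..20 and the 20 rank lists are
   merged by counting each feature's appearances in the per-list top-50;
   ties are broken by smaller mean rank across lists, then feature index.
2. **Cost-sensitive SVM (CSVM).** A soft-margin SVM whose training
   objective multiplies the error penalty of the progressive class by a
   cost ratio ≥ 1 (default 52/24, which exactly re-balances the per-class
   penalty mass of the canonical cohort). Linear kernel by default;
   features are z-scored inside the model with training statistics only.
3. **Sequential forward selection.** Features are added in aggregated rank
   order; a candidate is kept iff the inner-cross-validated pooled F1
   (F1 = 2·precision·sensitivity/(precision+sensitivity)) strictly improves
   (absolute tolerance 1e-9), with C and the cost ratio re-tuned inside
   every candidate evaluation. The scan stops at the first rejected
   candidate (the literal reading of "until adding a new feature did not
   improve performance"); a skip-and-continue `mode="scan"` is available.
   At least one feature is always selected.

The outer LOOCV leaves one subject out per fold; ranking, selection, scaling
and tuning all run strictly on the 75 training subjects. Features selected
in at least `round(0.95 · n_folds)` outer folds (72 of 76 — the count the
nominal "95%" stability rule denotes on 76 folds, although 72/76 = 94.7%)
are called *contributive*; a refined model over only those features is
retrained on the full cohort and summarized by a ROC curve (threshold sweep
over the sorted unique decision scores with ±∞ endpoints) and its AUC
(Mann–Whitney rank formulation; ties count 1/2; verified identical to
trapezoidal integration of the ROC polyline).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `ReliefConfig.k_min/k_max/k_step` | 1/20/1 | neighbor-count grid; k must be ≤ smallest class − 1 |
| `ReliefConfig.top_m` | 50 | list depth for occurrence counting |
| `CsvmConfig.C` | 1.0 | SVM regularization weight |
| `CsvmConfig.cost_ratio` | 52/24 | progressive:stable error-penalty ratio |
| `CsvmConfig.C_grid` | {0.01, 0.1, 1, 10, 100} | inner-loop tuning grid |
| `CsvmConfig.ratio_grid` | {1, 52/24, 3, 5} | inner-loop tuning grid |
| stability threshold | 0.95 | contributive-feature rule (count-based, see above) |
| `inner_cv` | `"loo"` | inner evaluation protocol; an integer selects stratified k-fold |

Numerical conventions: feature-weight ranking breaks ties by ascending
feature index; neighbor ties in ReliefF distance break by subject index;
constant features contribute difference 0 (weight exactly 0) instead of
dividing by a zero range; a decision score of exactly 0 is classified
stable; F1 is 0 when precision + sensitivity = 0; zero-variance features
are dropped (with a warning) before SVM fitting.

## Cohort statistics

The descriptive battery mirrors a publication-style baseline table:
two-tailed independent-samples t-tests for continuous variables (pooled or
Welch; `auto` gates on Levene's mean-centered test at α = .05), 2×2
chi-square for dichotomous variables where `auto` applies the Yates
continuity correction iff any expected cell is < 5 (this rule reproduces
all five tabulated dichotomous statistics, which neither always-Pearson nor
always-Yates does), an ANCOVA-style partial-F group comparison for
covariate-adjusted outcomes (perfectly covariate-explained outcomes return
F = 0 rather than a 0/0 artifact), partial correlation by residualizing
both vectors on covariates + intercept (p from the t transform with
n − #covariates − 2 df; cross-checked against an independent library
implementation), and Bonferroni thresholds α/m. Because the battery mixes
statistic kinds, every result carries an explicit kind label
(`t_pooled`, `t_welch`, `chi2_pearson`, `chi2_yates`, `F_ancova`).

## Synthetic cohorts

Real cohort data of this kind is not redistributable, so the generator
produces cohorts with the structure the analysis assumes: 76 subjects
(24 progressive), 223 named features matching the canonical schema. Five
planted features carry the reported effect directions — education
(9.50 ± 3.06 stable vs 7.17 ± 4.15 progressive), baseline MoCA
(24.04 ± 3.90 vs 22.96 ± 4.49), baseline stroke prevalence (3/52 vs 4/24),
a smaller left amygdala and a larger right bankssts WM volume (the two MRI
effects use Cohen's d = 0.6 on plausible raw volume scales, since no group
volumes are tabulated). All other features are label-free noise with an
exchangeable background correlation (ρ = 0.2, a minimal stand-in for
real morphometric covariance). `effect_scale` multiplies every planted
group difference about the stable-group parameters (0 = exact null).
Binary features are drawn before continuous ones; WM and subcortical
blocks are re-normalized to sum to 1 per subject after planting, matching
assembled real data. Generation is bit-reproducible for a fixed seed
(numpy PCG64).

What the generator does **not** emulate: realistic inter-feature covariance
structure (atlas neighborhoods, left–right symmetry), non-Gaussian clinical
distributions (zero-inflated "years of disease" variables), and any
MoCA–education–age dependence. Passing recovery tests on these cohorts
therefore demonstrate that the pipeline machinery finds signal of the
planted kind at the configured strength under exchangeable noise — not
that the original cohort's effects are re-identifiable.

## Simulation problem sizes

The nested protocol's fidelity defaults (inner LOOCV, full tuning grids)
are quadratic-plus in the cohort size. The simulation studies in the test
suite and the acceptance script use a scaled protocol chosen a priori as
this package's study condition for repeated runs: stratified 3-fold inner
evaluation and reduced grids C ∈ {0.1, 1, 10}, cost ratio ∈ {1, 52/24, 3},
on full-size 76 × 223 cohorts. Single runs (e.g. the CLI) may use any
protocol.

## Behavior under the null and known limitations

- With the cost ratio near 52/24 the per-class penalty mass is balanced, so
  on label-permuted (null) cohorts the classifier's predictions are close
  to a fair coin: null LOOCV accuracy concentrates near 0.5, *below* the
  majority-class rate of 0.684 that a cost-insensitive classifier would
  approach. Measured mean over 20 permutations: ≈ 0.50. This is the
  expected signature of a leakage-free cost-sensitive pipeline (leakage
  would inflate null accuracy above the chance rate).
- The literal first-rejection stopping rule makes the selected set short:
  once the inner F1 saturates, lower-ranked informative features are never
  examined. On strongly separable synthetic cohorts, features ranked below
  the stopping point (the weakest planted effect, baseline MoCA, in
  particular) consequently rarely reach high outer-fold selection
  frequencies even though stronger planted features reach 1.0. This is a
  property of the selection design itself, faithfully implemented;
  `mode="scan"` trades it for a longer scan.
- The refined model's default resubstitution ROC is optimistically biased
  (the same subjects are scored that the model was retrained on); the
  `score_mode="loocv"` alternative is recommended when an honest estimate
  of discrimination is needed.
- LOOCV performance estimates are high-variance at n = 76; per-fold
  selected sets and tuned hyperparameters are frozen per fold and never
  pooled across folds.
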