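# scdprog

Machine-learning prediction of progression from **subjective cognitive
decline (SCD)** — self-experienced memory worsening with objectively normal
neuropsychological performance — to **amnestic mild cognitive impairment
(MCI)**, from baseline structural-MRI morphometry and clinical measurements.
Built for biostatisticians and neuroimaging researchers working with small,
imbalanced longitudinal cohorts (canonically 76 subjects, 24 progressive vs
52 stable, 25 clinical + 198 MRI features).

## What it implements

- **Feature assembly**: a 223-column subjects × features matrix from a
  clinical CSV/TSV plus per-subject FreeSurfer-style stats tables
  (Desikan–Killiany parcellation: 46 global volumes and 68 cortical
  thicknesses unnormalized; 68 white-matter and 16 subcortical volumes
  normalized by their block totals).
- **Ensemble ReliefF ranking**: deterministic ReliefF weights
  `W_f = E[ |x_f − x_f^{miss(k)}| − |x_f − x_f^{hit(k)}| ]` over a neighbor
  grid k = 1..20, aggregated into one order by top-50 occurrence frequency
  (ties: mean rank, then index).
- **Cost-sensitive SVM**: a soft-margin SVM whose objective weighs errors on
  the progressive class by a cost ratio ≥ 1 (default 52/24); z-scoring with
  training statistics only; continuous decision scores (positive =
  progressive).
- **Sequential forward selection** along the aggregated rank order, keeping
  a candidate iff the inner-CV pooled F1 strictly improves, with C and the
  cost ratio re-tuned per candidate; stops at the first rejection.
- **Nested leave-one-out cross-validation**: per-fold ranking + selection +
  tuning strictly on the training subjects; accuracy / sensitivity /
  specificity / F1 from the pooled confusion matrix; per-feature outer-fold
  selection frequencies; *contributive* features at the count-based 95%
  stability rule (72 of 76 folds); a refined model over those features with
  ROC and Mann–Whitney AUC.
- **Cohort statistics**: pooled/Welch t-tests (raw or summary input), 2×2
  chi-square with an automatic Yates rule (iff any expected cell < 5),
  ANCOVA-style adjusted group comparison, partial correlation, Bonferroni
  thresholds, and a publication-style group-comparison table.
- **Synthetic cohorts**: seeded generators with five planted effects
  (lower education, lower baseline MoCA, more baseline stroke, smaller
  left amygdala, larger right bankssts WM volume in progressors) so the
  whole pipeline is testable without any restricted data.

See `docs/methods.md` for the model details, defaults, and limitations.

## Worked example

```python
from scdprog import (
    SyntheticConfig, generate_cohort, ReliefConfig, CsvmConfig,
    nested_loocv, contributive_features, refined_model_and_roc,
    make_worked_confusion, compute_metrics, f1_score,
)

# the canonical printed confusion counts: 15/24 progressive, 38/52 stable
m = compute_metrics(make_worked_confusion())
print(f"{m['accuracy']:.2%} {m['sensitivity']:.2%} {m['specificity']:.2%} "
      f"F1={f1_score(make_worked_confusion()):.4f}")
# -> 69.74% 62.50% 73.08% F1=0.5660

# full pipeline on a synthetic cohort with 3x-strength planted effects
cohort = generate_cohort(SyntheticConfig(seed=1, effect_scale=3.0))
res = nested_loocv(
    cohort.matrix,
    relief_cfg=ReliefConfig(),                     # k = 1..20, top-50
    csvm_cfg=CsvmConfig(C_grid=(0.1, 1, 10), ratio_grid=(1, 52/24, 3)),
    inner_cv=3,                                    # scaled inner protocol
)
print(res.metrics["accuracy"])                     # -> 0.9473...
contrib = contributive_features(res.selection_frequency, res.n_folds)
print(contrib)                                     # -> ['education', 'stroke_baseline']
refined = refined_model_and_roc(cohort.matrix, contrib)
print(round(refined.auc, 4))                       # -> 0.9824
```

The nested LOOCV recovers the planted signal (94.7% accuracy vs a 68.4%
majority rate); the two features stable across ≥ 72 of 76 outer folds form
the refined model, whose resubstitution AUC is 0.98 on this cohort.

A thin CLI wraps the same functions:

```bash
scdprog synth --seed 1 --effect-scale 3 --out cohort.csv --truth-out truth.json
scdprog run --features cohort.csv --inner-cv 3 --out results.json
```

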