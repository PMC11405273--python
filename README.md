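# protrisk

Sparse protein-based risk prediction for incident disease, built and
validated on synthetic plasma-proteomics cohorts.

Large proteomic biobank studies ask whether a handful of circulating
proteins can improve 10-year disease risk prediction over basic clinical
information (age, sex, BMI, ethnicity, smoking, alcohol, family history).
The data behind such studies are access-controlled, so `protrisk` pairs the
full discovery-and-validation machinery with a synthetic-cohort generator
whose sparse signal structure is known exactly — every stage of the
pipeline can be tested against ground truth on one workstation.

## The method

For each disease with enough incident cases (> 80 within the horizon, after
excluding prevalent cases and events in the first 6 months):

1. **Split.** Case-stratified partition: 50% feature selection / 25%
   optimization / 25% validation when cases > 800, otherwise 70% / 30%.
2. **Select.** On the selection split, repeat (default 200×): subsample
   without replacement, rebalance cases vs controls by a smoothed bootstrap
   (ROSE-style Gaussian kernels with per-feature bandwidth
   h_j = σ̂_j·(4/((d+2)n))^(1/(d+4))), tune the L1 penalty λ by repeated
   k-fold cross-validation, and add |β̂_j(λ_opt)| to assay j's *selection
   score*. The top 20 assays go forward.
3. **Optimize.** Regularized Cox models (Breslow ties, λ by cross-validated
   partial likelihood): a clinical benchmark, clinical + top-20 proteins
   (clinical covariates unpenalized), clinical + top-10/5 (ranked by
   |optimized weight| × selection score), and top-5 proteins alone.
4. **Validate.** Harrell's C over 1,000 paired bootstrap resamples of the
   held-out validation split; an augmented model is an improvement when the
   95% CI of the per-replicate ΔC excludes zero. Screening utility is read
   off DR/FPR curves (LR = DR/FPR, thresholds at control-score quantiles
   from 5% to 40% FPR), post-test probabilities, category-free NRI with a
   0.15 risk-difference margin, and IDI. Stratified (sex, age-of-onset),
   5-year-horizon and case-downsampled evaluations reuse the same machinery.

Supporting stages: 5-s.d. PC/median-NPX/IQR sample QC, per-panel iterative
random-forest imputation (50 trees per forest, age and sex as extra
predictors), Fisher/BH annotation enrichment, and cross-disease
predictor-sharing summaries.

## Worked example

```python
import pandas as pd
from protrisk import (CohortConfig, generate_cohort, apply_incidence_filters,
                      make_splits, subsampled_selection, rank_top_k,
                      fit_model_suite, predict_risk, bootstrap_compare,
                      screening_curve, SelectionConfig)

cfg = CohortConfig(n_samples=4000, n_assays=600, n_panels=4, block_size=10,
                   block_rho=0.3, causal_assays=(3, 130, 260, 390, 520),
                   beta_protein=(0.5, -0.75, 1.0, -1.25, 1.5),
                   target_case_count=400, prevalent_frac=0.02, seed=2024)
matrix, covariates, outcomes, truth = generate_cohort(cfg)
kept, _ = apply_incidence_filters(outcomes)          # prevalent + <6-month exclusions
splits = make_splits(kept, seed=2024)                # 70/30 (≤800 cases)

sel = splits.selection_ids.intersection(kept.sample_ids)
scores = subsampled_selection(
    matrix.values.loc[sel], kept,
    SelectionConfig(n_iterations=50, cv_folds=3, cv_repeats=1,
                    n_lambda=12, lambda_min_ratio=0.05,
                    rebalance_size=800, seed=2024))
print(rank_top_k(scores, 5))
suite = fit_model_suite(matrix, covariates, kept, splits, scores, seed=2024)

val = splits.validation_ids.intersection(kept.sample_ids)
feats = pd.concat([covariates.design_matrix(), matrix.values], axis=1).loc[val]
lp_clin = predict_risk(suite["clinical"], feats)["linear_predictor"]
lp_prot = predict_risk(suite["clinical_proteins_5"], feats)["linear_predictor"]
_, _, d = bootstrap_compare(lp_clin, lp_prot, kept.subset(val), B=1000, seed=2024)
print(f"delta C = {d.delta_mean:.3f} (95% CI {d.ci_low:.3f} to {d.ci_high:.3f})")
print(screening_curve(lp_prot, kept.subset(val)).at_fpr(0.10)[["dr", "lr"]])
```

prints (seed 2024):

```
['A0521', 'A0391', 'A0261', 'A0131', 'A0004']
delta C = 0.394 (95% CI 0.337 to 0.450)
dr    0.85567
lr    8.58899
```

The five causal assays (`A0004`, `A0131`, `A0261`, `A0391`, `A0521` — the
1-based ids of the configured indices) are recovered exactly, ordered by
their true effect sizes. The sparse five-protein model lifts the validation
C-index by 0.39 over the clinical benchmark, with a bootstrap CI far from
zero; at a 10% false positive rate it detects 86% of incident cases
(LR ≈ 8.6), so a positive test multiplies the pre-test odds almost
nine-fold.

The numbered drivers under `analysis/` run the same study as a narrative —
`01_simulate_cohort.py` through `06_enrichment_report.py` — writing compact
tables to `results/` (bulky regenerable matrices go to `scratch/`).

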