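# Methods

## The generative model

The cohort generator draws a samples × assays matrix of NPX-like log2
relative abundances from equicorrelated Gaussian blocks nested within
panels: within a block of size *m*, every pair of assays has correlation
ρ (via a shared latent factor, `X = √ρ·Z + √(1−ρ)·ε`), and blocks are
independent. Real inter-protein covariance in plasma is not public;
equicorrelated blocks were chosen because they reproduce the failure mode
that matters for L1 selection — strongly correlated assays competing for a
shared coefficient — while remaining positive definite for any ρ ∈ [0, 1)
and cheap to sample. Panels exist so per-panel operations (imputation,
plate-style missingness) have real structure to work on.

Clinical covariates are drawn marginally (age ~ U(40, 70) years;
sex ~ Bernoulli(½); BMI ~ N(27.3, 4.7²) kg/m², clipped to [16, 55];
ethnicity/smoking/alcohol categorical with biobank-typical frequencies;
family history Bernoulli(0.12), optionally tilted by the true risk through
`family_history_assoc`). Their log hazard ratios apply to standardized age
and BMI, centred sex, and the current-smoker indicator; defaults
(0.35, 0.2, 0.15, 0.25) give the clinical benchmark a true concordance
near 0.6 — weak but clearly non-null, as for most incident diseases.

Event times follow a proportional-hazards law with cumulative hazard
`r·t^k·exp(lp)`, `lp = Xβ_protein + C·β_clinical`; the default shape
k = 1 (exponential) keeps case-count calibration closed-form, Weibull
shapes are available. Censoring is administrative at the horizon (default
10 years) with optional uniform dropout; the real study's censoring beyond
the administrative cutoff is unknown, so dropout is off by default. When a
target case count is given, the baseline rate is found by bisection on
`Σ(1 − exp(−r·e^lp·τ^k))` to a 1% relative tolerance — diseases in the
source setting are characterized by observed counts, not rates. A
configurable fraction of samples is flagged prevalent (time 0, no incident
event) to exercise the inclusion filters. Everything is reproducible
bit-for-bit from the config seed.

What the generator does *not* emulate: assay-specific limits of detection,
plate/batch effects surviving normalization, non-proportional hazards,
informative censoring, competing risks, and non-Gaussian abundance tails.
Passing tests therefore demonstrate correctness of the machinery and its
statistical calibration under a clean PH world, not performance claims
about any real cohort.

## Inclusion filters and splits

Prevalent cases and incident cases within the first 6 months of follow-up
are removed (the 6-month window is half-open: an event at exactly 6 months
is retained). Diseases below 80 incident cases are refused. The partition
is 50/25/25 (selection/optimization/validation) when incident cases
exceed 800, otherwise 70/30 with the 70% serving both selection and
optimization; splits are stratified by case status — the source procedure
does not say whether it stratified, but unstratified splits at rare-disease
case counts can leave a part nearly caseless, which only adds variance.

## QC and imputation

A sample is an outlier if its standardized PC1 or PC2 score, its median
NPX, or its IQR of NPX lies more than 5 s.d. from the cohort mean. PCA is
computed once across all assays jointly (the per-panel alternative is
plausible but was not indicated), on standardized assays with mean-filled
missing cells; the fill affects only the PCA. All-missing samples are
flagged, not fatal.

Imputation is a missForest-style loop per panel: initialize missing cells
at assay means, visit assays by ascending missingness, regress each on the
other assays of its panel plus age and sex with a 50-tree random forest,
and stop the first time the normalized sum of squared changes in the
imputed cells increases, returning the previous iterate (the classic
stopping rule; the named algorithm's variant was not specified further).
mtry and depth are library defaults (√p, unbounded). One deviation: the
reference forests grow trees on without-replacement subsamples; sklearn's
forests only bootstrap, so trees here see with-replacement draws of
fraction `sampling` (default 0.9) of the rows. The difference perturbs
individual tree training sets, not the regression target, and the
imputation benchmark (NRMSE strictly below mean-fill on ρ = 0.6 blocks
with 10% MCAR, every seed) is insensitive to it. Samples over 50% missing
are rejected before imputation; observed cells are never modified (exact
equality, tested).

## Selection stage

The per-iteration model is L1-penalized **logistic** regression on the
binary "incident within horizon" label. The rebalancing step the procedure
calls for is defined for class labels and has no natural censored-data
analogue, and the "regularized Cox" language is reserved for the
optimization stage — so logistic is the default, with an L1 Cox variant
(no rebalancing) behind `model="cox"`. Controls for the label are samples
event-free *at* the horizon; early-censored non-events are excluded as
label-ambiguous.

Each iteration subsamples 80% of the selection split without replacement
(fraction unstated in the source; 80% is the common stability-selection
choice), rebalances to p = 0.5 with the smoothed bootstrap (per-feature,
per-class bandwidth `h_j = shrink·σ̂_j·(4/((d+2)n))^(1/(d+4))`, the
multivariate Silverman factor; shrink = 1), standardizes, tunes λ by
repeated stratified k-fold cross-validated binomial deviance over a
log-spaced grid from λ_max down to `lambda_min_ratio·λ_max`, refits at
λ_opt, and adds |β̂_j| to assay j's score. Defaults are the full-scale
settings (200 iterations, 5×3 CV, 50-point grid to 10⁻³λ_max).

The λ path is computed with sequential strong-rule screening: candidate
columns are those passing the gradient bound `|x_jᵀ(y−p)|/n ≥ 2λ_k−λ_{k−1}`
plus the previous active set; the inner solver (liblinear, seeded) fits
only those columns and KKT conditions are verified on the rest, with
violators re-admitted. Coefficients match direct full-matrix fits to ~10⁻⁵
at a ~16× speedup, which is what makes hundreds of CV'd iterations
feasible on one CPU.

Ranking: top-k by score, ties broken lexicographically by assay id;
zero-score assays are never returned (with a warning if k exceeds the
positive-score count). The 10- and 5-assay signatures rank model features
by |optimized Cox weight| × selection score; unpenalized clinical
covariates are never ranked and always retained.

## Risk models

`fit_penalized_cox` standardizes features, fits an L1 Cox path
(coordinate-descent Coxnet; Breslow ties throughout), and picks λ by
k-fold cross-validated partial likelihood in the Verweij–Van Houwelingen
form, `pl(all; β_train) − pl(train; β_train)`: scoring the small held-out
fold's own partial likelihood directly proved noisy enough at desk scale
to shrink genuinely informative clinical models to zero. A grid of `[0.0]`
requests an unpenalized Newton fit. If the coordinate descent diverges at
the dense end of the path (possible with unpenalized covariates), the
small-λ tail is truncated and the fit retried.

In augmented models the clinical covariates carry no penalty
(penalty factor 0), so proteins must earn coefficients on top of — not
instead of — the benchmark; the benchmark clinical model itself is
penalized with CV'd λ like any other member. Categorical covariates are
one-hot encoded against a first-level reference. The suite records each
member's validation concordance and marks the best of the 5/10/20 protein
models. Absolute risk at the horizon is `1 − exp(−H₀·e^lp)` with H₀ the
Breslow cumulative baseline hazard at the horizon from the training split.
Models serialize to JSON (features, β, standardization, H₀, horizon) and
reload to bit-identical predictions — the frozen-weight transfer mechanism
used for external-cohort replication.

## Evaluation

Concordance follows Harrell: a pair is comparable iff the earlier time is
an event; tied scores count ½; tied times are never comparable (tested
against brute-force pair enumeration, including ties). Bootstrap
comparison draws the *same* resample for both models (paired — required
for a coherent difference distribution), expressed as multinomial weights
w so each replicate's C is the quadratic form `(wᵀKw)/(wᵀMw)` over
precomputed pair matrices (O(n²) per replicate instead of re-enumeration);
replicates without comparable pairs are redrawn. ΔC's 95% CI is the
empirical 2.5/97.5 percentile band; "significant" means the CI excludes
zero, and the directional "significant improvement" used by the
calibration studies means the CI lies entirely above zero.

Screening curves set thresholds at control-score quantiles: at target FPR
f, the threshold is the (k+1)-th largest control score, k = ⌊f·n_controls⌋,
so realized FPR matches the target up to discreteness and LR = DR/FPR holds
exactly on the realized counts (reported alongside the targets). Cases are
events within the horizon; controls are event-free with follow-up reaching
the horizon; early-censored non-events are excluded from these binary
metrics (the source rule is unstated; the choice is switchable by passing a
different status rule upstream). cNRI uses a 0.15 risk-difference margin;
IDI is the gain in discrimination slope; both are plain (non-IPCW)
estimators — appropriate under the simulation's administrative censoring,
and an explicit extension point for Kaplan–Meier-weighted variants.
Stratified evaluation skips strata under 20 incident cases and reports
them as skipped. Alternate-horizon (e.g. 5-year) evaluation changes only
the horizon argument. Case downsampling keeps a uniform random case subset
plus all non-cases.

## Enrichment and reporting

Per-label 2×2 tables (selected × labelled against a background assay set)
are tested with the two-sided Fisher exact test; odds ratios are sample
ORs with a Haldane 0.5 correction when a cell is zero; BH adjustment is
standard step-up. The sharing summary normalizes each disease's weights to
its top predictor, counts diseases and specialties per assay, and flags
assays selected for exactly one disease with normalized weight > 0.6 as
disease-specific.

## Study conditions (tests and the acceptance script)

Desk-scale conditions, chosen once: the recovery study uses n = 4,000,
600 assays (blocks of 10, ρ = 0.3), five causal proteins with |log HR|
0.5–1.5, ~400 incident cases at 10 years, 50 selection iterations with
3-fold single-repeat CV over a 12-point grid to 0.05·λ_max and rebalanced
draws of 800, over 10 seeds. The null study uses n = 2,000, 200 assays,
~200 cases, 15 iterations, 20 seeds. The imputation study uses n = 220,
16 assays (ρ = 0.6), 10% MCAR, 10 seeds. Bootstrap comparisons use
B = 1,000. The analysis drivers run the same reference disease once at
seed 2024.

## Known limitations

The selection stage's logistic reading of the rebalanced step is one of
two defensible interpretations (the Cox variant is provided but not the
default). cNRI/IDI are unweighted and would need IPCW under informative
censoring. The generator's clean PH world understates real-data
difficulties (batch effects, LOD censoring, competing risks), so absolute
performance numbers here do not transfer to any real cohort — the package
validates machinery and calibration, not clinical claims.
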