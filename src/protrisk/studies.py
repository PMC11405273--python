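"""Reference simulation studies over the full pipeline.

Each study fixes cohort-generating conditions and runs the complete chain —
simulate, filter, split, select, fit, validate — over several seeds, so the
same computations back the analysis drivers, the test suite and the results
reproduction script.  Problem sizes are desk-scale by design: large enough
for the qualitative behaviour (sparse-signal recovery, null calibration,
imputation gain) to be stable across seeds, small enough to run on one CPU
in minutes; library defaults remain the full-scale settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortConfig, apply_incidence_filters, generate_cohort, inject_missingness
from .evaluation import (
    DeltaCResult,
    bootstrap_compare,
    post_test_probability,
    screening_curve,
)
from .impute import ImputationConfig, iterative_rf_impute, mean_impute, nrmse
from .risk import fit_model_suite, predict_risk
from .selection import SelectionConfig, make_splits, rank_top_k, subsampled_selection

__all__ = [
    "fast_selection_config",
    "run_disease_pipeline",
    "recovery_study",
    "null_calibration_study",
    "imputation_study",
    "celiac_screening_example",
    "null_screening_check",
]

# Five causal proteins with |log HR| spanning 0.5–1.5 per s.d. of NPX,
# placed in distinct correlation blocks on distinct panels.
RECOVERY_BETAS = (0.5, -0.75, 1.0, -1.25, 1.5)
RECOVERY_CAUSAL_AT = (3, 130, 260, 390, 520)


def fast_selection_config(n_iterations: int, seed: int) -> SelectionConfig:
    """Desk-scale selection settings: 3-fold single-repeat CV, a 12-point
    penalty grid spanning the sparse regime (down to 0.05 lambda_max), and
    rebalanced draws of 800 rows."""
    return SelectionConfig(
        n_iterations=n_iterations,
        subsample_fraction=0.8,
        cv_folds=3,
        cv_repeats=1,
        n_lambda=12,
        lambda_min_ratio=0.05,
        rebalance_size=800,
        seed=seed,
    )


@dataclass
class PipelineResult:
    seed: int
    n_cases: int
    top20: list[str]
    n_causal_recovered: int
    validation_c: dict[str, float]
    delta_top5_vs_clinical: DeltaCResult
    best_protein_model: str


def run_disease_pipeline(
    config: CohortConfig,
    selection_config: SelectionConfig,
    cv_folds: int = 3,
    bootstrap_B: int = 1000,
) -> PipelineResult:
    """One full discovery-and-validation run on a synthetic disease."""
    matrix, covariates, outcomes, truth = generate_cohort(config)
    filtered, _ = apply_incidence_filters(outcomes)
    splits = make_splits(filtered, seed=config.seed)

    sel_ids = splits.selection_ids.intersection(filtered.sample_ids)
    scores = subsampled_selection(matrix.values.loc[sel_ids], filtered, selection_config)
    top20 = rank_top_k(scores, 20)
    causal = set(truth.causal_assays)
    n_recovered = len(causal & set(top20))

    suite = fit_model_suite(
        matrix, covariates, filtered, splits, scores,
        cv_folds=cv_folds, seed=config.seed, top_k_grid=(20, 10, 5),
    )
    val_ids = splits.validation_ids.intersection(filtered.sample_ids)
    features = pd.concat([covariates.design_matrix(), matrix.values], axis=1).loc[val_ids]
    lp_clin = predict_risk(suite["clinical"], features)["linear_predictor"]
    lp_top5 = predict_risk(suite["clinical_proteins_5"], features)["linear_predictor"]
    _, _, delta = bootstrap_compare(
        lp_clin, lp_top5, filtered.subset(val_ids), B=bootstrap_B, seed=config.seed
    )
    return PipelineResult(
        seed=config.seed,
        n_cases=filtered.n_incident_cases,
        top20=top20,
        n_causal_recovered=n_recovered,
        validation_c=suite.validation_c,
        delta_top5_vs_clinical=delta,
        best_protein_model=suite.best_protein_model,
    )


def recovery_study(
    seed: int = 0,
    n_seeds: int = 10,
    n_samples: int = 4000,
    n_assays: int = 600,
    block_rho: float = 0.3,
    target_cases: int = 400,
    n_iterations: int = 50,
) -> dict:
    """Sparse-signal recovery under the reference conditions: five causal
    proteins (|log HR| 0.5–1.5) among correlated nulls, ~400 cases at 10 y.

    Reports, per seed, how many of the five causal assays reach the top-20
    selection and whether clinical+top-5 significantly beats clinical."""
    results: list[PipelineResult] = []
    for i in range(n_seeds):
        cfg = CohortConfig(
            n_samples=n_samples,
            n_assays=n_assays,
            n_panels=4,
            block_size=10,
            block_rho=block_rho,
            causal_assays=RECOVERY_CAUSAL_AT,
            beta_protein=RECOVERY_BETAS,
            target_case_count=target_cases,
            prevalent_frac=0.02,
            seed=seed * 1000 + i,
        )
        results.append(
            run_disease_pipeline(cfg, fast_selection_config(n_iterations, seed * 1000 + i))
        )
    recovered = np.array([r.n_causal_recovered for r in results])
    sig = np.array([r.delta_top5_vs_clinical.significant_improvement for r in results])
    return {
        "per_seed": results,
        "recovery_rate": float((recovered >= 4).mean()),
        "mean_causal_in_top20": float(recovered.mean()),
        "significant_improvement_rate": float(sig.mean()),
        "mean_delta_c": float(np.mean([r.delta_top5_vs_clinical.delta_mean for r in results])),
    }


def null_calibration_study(
    seed: int = 0,
    n_seeds: int = 20,
    n_samples: int = 2000,
    n_assays: int = 200,
    target_cases: int = 200,
    n_iterations: int = 15,
) -> dict:
    """All-null cohorts (every protein effect zero): the pipeline should
    declare a significant protein improvement (delta-C CI entirely above 0)
    in at most about the nominal 5% of seeds."""
    results: list[PipelineResult] = []
    for i in range(n_seeds):
        cfg = CohortConfig(
            n_samples=n_samples,
            n_assays=n_assays,
            n_panels=4,
            block_size=10,
            block_rho=0.3,
            causal_assays=(),
            beta_protein=(),
            target_case_count=target_cases,
            seed=seed * 1000 + i,
        )
        results.append(
            run_disease_pipeline(cfg, fast_selection_config(n_iterations, seed * 1000 + i))
        )
    sig = np.array([r.delta_top5_vs_clinical.significant_improvement for r in results])
    return {
        "per_seed": results,
        "significant_improvement_fraction": float(sig.mean()),
        "mean_delta_c": float(np.mean([r.delta_top5_vs_clinical.delta_mean for r in results])),
    }


def imputation_study(
    seed: int = 0,
    n_seeds: int = 10,
    n_samples: int = 220,
    n_assays: int = 16,
    block_rho: float = 0.6,
    missing_rate: float = 0.10,
) -> dict:
    """Iterative random-forest vs assay-mean imputation on block-correlated
    data with MCAR missingness, scored by NRMSE on the masked cells."""
    pairs = []
    for i in range(n_seeds):
        cfg = CohortConfig(
            n_samples=n_samples,
            n_assays=n_assays,
            n_panels=2,
            block_size=n_assays // 2,
            block_rho=block_rho,
            baseline_rate=0.01,
            seed=seed * 1000 + i,
        )
        matrix, covariates, _, _ = generate_cohort(cfg)
        masked = inject_missingness(matrix, missing_rate, "MCAR", seed=seed * 1000 + i)
        rf = iterative_rf_impute(masked, covariates, ImputationConfig(seed=seed * 1000 + i))
        mean = mean_impute(masked)
        pairs.append(
            (nrmse(rf, matrix, masked.missing_mask), nrmse(mean, matrix, masked.missing_mask))
        )
    rf_vals = np.array([p[0] for p in pairs])
    mean_vals = np.array([p[1] for p in pairs])
    return {
        "rf_nrmse": rf_vals,
        "mean_nrmse": mean_vals,
        "rf_beats_mean_all_seeds": bool((rf_vals < mean_vals).all()),
        "mean_nrmse_ratio": float((rf_vals / mean_vals).mean()),
    }


def celiac_screening_example() -> dict:
    """The published worked example for a celiac-disease screening test:
    a validation set in which 80.8% of cases and exactly 10% of controls
    exceed the test threshold.  The screening-curve machinery must recover
    LR = DR/FPR = 8.08 at the 10% FPR grid point, and a 1% pre-test
    probability must map to a 7.55% post-test probability."""
    from .cohort import OutcomeTable

    n_cases, n_controls = 1000, 1000
    dr = 0.808
    # distinct control scores so the quantile threshold is exact
    control_scores = np.arange(n_controls, dtype=float)
    case_scores = np.where(np.arange(n_cases) < int(round(dr * n_cases)), 2000.0, -1.0)
    scores = np.concatenate([case_scores, control_scores])
    table = pd.DataFrame(
        {
            "time_years": np.r_[np.full(n_cases, 5.0), np.full(n_controls, 10.0)],
            "event": np.r_[np.ones(n_cases, int), np.zeros(n_controls, int)],
            "prevalent": np.zeros(n_cases + n_controls, int),
        },
        index=pd.Index([f"S{i}" for i in range(n_cases + n_controls)], name="sample_id"),
    )
    outcomes = OutcomeTable(table, horizon_years=10.0)
    curve = screening_curve(scores, outcomes)
    at10 = curve.at_fpr(0.10)
    return {
        "curve": curve,
        "dr_at_10pct_fpr": float(at10["dr"]),
        "lr_at_10pct_fpr": float(at10["lr"]),
        "post_test_probability_1pct_pretest": post_test_probability(float(at10["lr"]), 0.01),
    }


def null_screening_check(seed: int = 0, n_samples: int = 6000, case_frac: float = 0.10) -> dict:
    """A random score on a null cohort: DR should track FPR (within 3
    binomial s.e.) at every grid point and LR should sit near 1."""
    from .cohort import OutcomeTable

    rng = np.random.default_rng(seed)
    n_cases = int(case_frac * n_samples)
    table = pd.DataFrame(
        {
            "time_years": np.r_[rng.uniform(0.5, 10.0, n_cases), np.full(n_samples - n_cases, 10.0)],
            "event": np.r_[np.ones(n_cases, int), np.zeros(n_samples - n_cases, int)],
            "prevalent": np.zeros(n_samples, int),
        },
        index=pd.Index([f"S{i}" for i in range(n_samples)], name="sample_id"),
    )
    outcomes = OutcomeTable(table, horizon_years=10.0)
    curve = screening_curve(rng.standard_normal(n_samples), outcomes)
    se = np.sqrt(curve.table["fpr"] * (1 - curve.table["fpr"]) / n_cases)
    return {
        "curve": curve,
        "max_abs_dr_minus_fpr": float((curve.table["dr"] - curve.table["fpr"]).abs().max()),
        "within_3se": bool(((curve.table["dr"] - curve.table["fpr"]).abs() <= 3 * se).all()),
        "mean_lr": float(curve.table["lr"].mean()),
        "n_cases": n_cases,
    }
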