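"""Iterative random-forest imputation of missing protein values.

missForest-style loop, run separately per assay panel: missing cells are
initialized with assay means; assays are visited in order of ascending
missingness; for each assay a random forest is trained on the rows where it
is observed (predictors: the other assays of the panel at their current
imputed values, plus age and sex) and used to predict the missing rows.  The
loop stops the first time the normalized sum of squared changes in the
imputed cells increases, and the matrix from the previous iteration is
returned.  Observed cells are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .cohort import ClinicalCovariates, ProteinMatrix

__all__ = ["ImputationConfig", "iterative_rf_impute", "mean_impute", "nrmse"]


@dataclass
class ImputationConfig:
    trees_per_forest: int = 50
    max_iterations: int = 10
    sampling: float = 0.9  # per-tree subsample fraction
    per_panel: bool = True
    extra_predictors: tuple[str, ...] = ("age", "sex")
    max_sample_missing_frac: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.trees_per_forest < 1:
            raise ValueError("trees_per_forest must be >= 1")
        if not 0.0 < self.sampling <= 1.0:
            raise ValueError("sampling must lie in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def mean_impute(matrix: ProteinMatrix) -> ProteinMatrix:
    """Assay-mean fill; the baseline the forest must beat."""
    obs = matrix.observed()
    filled = obs.fillna(obs.mean())
    return ProteinMatrix(filled, matrix.panel_of.copy(), matrix.missing_mask.copy() & False)


def nrmse(imputed: ProteinMatrix, truth: ProteinMatrix, mask: pd.DataFrame) -> float:
    """Normalized RMSE over masked cells: RMSE divided by the s.d. of the
    true values at those cells."""
    m = mask.to_numpy()
    if not m.any():
        raise ValueError("mask selects no cells")
    diff = imputed.values.to_numpy()[m] - truth.values.to_numpy()[m]
    denom = truth.values.to_numpy()[m].std()
    return float(np.sqrt(np.mean(diff**2)) / denom)


def _impute_panel(
    X: np.ndarray,
    miss: np.ndarray,
    extra: np.ndarray,
    cfg: ImputationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """missForest loop for one panel; returns the imputed value matrix."""
    n, p = X.shape
    cur = X.copy()
    col_means = np.array([X[~miss[:, j], j].mean() for j in range(p)])
    for j in range(p):
        cur[miss[:, j], j] = col_means[j]

    order = np.argsort(miss.sum(axis=0), kind="stable")
    order = [j for j in order if miss[:, j].any()]
    if not order:
        return cur

    prev_diff = np.inf
    max_samples = None if cfg.sampling >= 1.0 else cfg.sampling
    for _ in range(cfg.max_iterations):
        before = cur.copy()
        for j in order:
            obs_rows = ~miss[:, j]
            predictors = np.column_stack([np.delete(cur, j, axis=1), extra])
            rf = RandomForestRegressor(
                n_estimators=cfg.trees_per_forest,
                max_samples=max_samples,
                bootstrap=True,
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            )
            rf.fit(predictors[obs_rows], cur[obs_rows, j])
            cur[miss[:, j], j] = rf.predict(predictors[miss[:, j]])
        changed = miss
        diff = float(np.sum((cur[changed] - before[changed]) ** 2) / max(np.sum(cur[changed] ** 2), 1e-12))
        if diff >= prev_diff:
            return before  # degradation: keep the previous iteration
        prev_diff = diff
    return cur


def iterative_rf_impute(
    matrix: ProteinMatrix, covariates: ClinicalCovariates, config: ImputationConfig | None = None
) -> ProteinMatrix:
    """Impute all masked cells; returns a matrix with an all-False mask.

    Raises if any assay has no observed value, or if any sample exceeds the
    per-sample missingness ceiling (default 50%), listing the offenders.
    """
    cfg = config or ImputationConfig()
    cfg.validate()
    mask = matrix.missing_mask.to_numpy()
    values = matrix.values.to_numpy(dtype=float).copy()
    values[mask] = np.nan

    fully_missing = matrix.assay_ids[mask.all(axis=0)]
    if len(fully_missing):
        raise ValueError(f"assay fully missing: {fully_missing[0]}")
    frac = mask.mean(axis=1)
    bad = matrix.sample_ids[frac > cfg.max_sample_missing_frac]
    if len(bad):
        raise ValueError(f"samples exceed {cfg.max_sample_missing_frac:.0%} missingness: {list(map(str, bad))}")

    clin = covariates.table.loc[matrix.sample_ids]
    extra = np.column_stack(
        [clin[c].to_numpy(float) for c in cfg.extra_predictors]
    ) if cfg.extra_predictors else np.empty((len(clin), 0))

    rng = np.random.default_rng(cfg.seed)
    out = values.copy()
    panels = matrix.panel_of.loc[matrix.assay_ids].to_numpy()
    groups = list(dict.fromkeys(panels)) if cfg.per_panel else ["__all__"]
    for pn in groups:
        cols = np.flatnonzero(panels == pn) if cfg.per_panel else np.arange(values.shape[1])
        sub = values[:, cols]
        sub_miss = mask[:, cols]
        imputed = _impute_panel(np.nan_to_num(sub, nan=0.0), sub_miss, extra, cfg, rng)
        # restore exact observed values (nan_to_num touched only masked cells,
        # but be explicit)
        imputed[~sub_miss] = matrix.values.to_numpy()[:, cols][~sub_miss]
        out[:, cols] = imputed

    result = pd.DataFrame(out, index=matrix.sample_ids, columns=matrix.assay_ids)
    return ProteinMatrix(result, matrix.panel_of.copy(), matrix.missing_mask.copy() & False)
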