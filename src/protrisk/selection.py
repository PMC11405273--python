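"""Stability-style feature selection for sparse risk signatures.

The selection stage follows the three-step framework's first step: the
retained cohort is split (50/25/25 above 800 incident cases, 70/30 below);
on the selection split, an L1-penalized model is fit on each of
``n_iterations`` subsamples (default 200), with smoothed-bootstrap class
rebalancing of cases vs controls and a repeated-cross-validation grid search
for the penalty; each assay's selection score accumulates the absolute
coefficient at the optimal penalty across iterations.  Top-k ranking and the
weight-times-score product rule sparsify the signature to 20/10/5 assays.

The per-iteration model is L1 logistic regression on the binary
"incident within horizon" label (the rebalancing step is defined for class
labels); an L1 Cox variant is available behind ``model="cox"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .cohort import OutcomeTable, ProteinMatrix

__all__ = [
    "SplitScheme",
    "SelectionConfig",
    "SelectionScoreTable",
    "make_splits",
    "binary_label_at_horizon",
    "smoothed_bootstrap_rebalance",
    "subsampled_selection",
    "rank_top_k",
    "sparsify_by_weight_product",
]


# ---------------------------------------------------------------------------
# splits

THREE_WAY_CASE_THRESHOLD = 800
MIN_INCIDENT_CASES = 80


@dataclass
class SplitScheme:
    """Disjoint selection / optimization / validation sample-id sets.

    Under the ``two_way`` rule (<= 800 cases) a single 70% set serves both
    selection and optimization; ``optimization_ids`` is then empty and
    consumers should fall back to ``selection_ids``.
    """

    selection_ids: pd.Index
    optimization_ids: pd.Index
    validation_ids: pd.Index
    rule: str  # "three_way" | "two_way"

    @property
    def training_ids(self) -> pd.Index:
        """Ids to fit risk models on: the optimization split, or the combined
        selection+optimization set under the two-way rule."""
        return self.optimization_ids if self.rule == "three_way" else self.selection_ids


def make_splits(outcomes: OutcomeTable, seed: int = 0) -> SplitScheme:
    """Case-stratified random partition per the >800-case rule."""
    t = outcomes.table
    cases = t.index[t["event"] == 1]
    controls = t.index[t["event"] == 0]
    n_cases = len(cases)
    if n_cases < MIN_INCIDENT_CASES:
        raise ValueError(
            f"{n_cases} incident cases: below the inclusion floor of {MIN_INCIDENT_CASES}"
        )
    rng = np.random.default_rng(seed)
    fractions = (0.5, 0.25, 0.25) if n_cases > THREE_WAY_CASE_THRESHOLD else (0.7, 0.3)

    parts: list[list] = [[] for _ in fractions]
    for ids in (cases, controls):
        perm = ids[rng.permutation(len(ids))]
        bounds = np.cumsum([int(round(f * len(ids))) for f in fractions[:-1]])
        for part, chunk in zip(parts, np.split(np.asarray(perm), bounds)):
            part.extend(chunk)
    if len(fractions) == 3:
        return SplitScheme(pd.Index(parts[0]), pd.Index(parts[1]), pd.Index(parts[2]), "three_way")
    return SplitScheme(pd.Index(parts[0]), pd.Index([]), pd.Index(parts[1]), "two_way")


def binary_label_at_horizon(outcomes: OutcomeTable, horizon: float | None = None) -> pd.Series:
    """Case = incident event within the horizon; control = event-free with
    follow-up reaching the horizon.  Early-censored non-events are excluded
    (they are label-ambiguous)."""
    horizon = outcomes.horizon_years if horizon is None else horizon
    t = outcomes.table
    case = (t["event"] == 1) & (t["time_years"] <= horizon)
    control = (t["event"] == 0) & (t["time_years"] >= horizon)
    labels = pd.Series(np.where(case, 1, 0), index=t.index)[case | control]
    return labels


# ---------------------------------------------------------------------------
# smoothed-bootstrap rebalancing (ROSE-style)


def _rose_bandwidth(sigma: np.ndarray, n_class: int, d: int, shrink: float) -> np.ndarray:
    """Per-feature Gaussian kernel bandwidth h_j = shrink * sigma_j *
    (4 / ((d + 2) n))^(1/(d+4)) — the multivariate Silverman factor used by
    smoothed-bootstrap oversampling."""
    return shrink * sigma * (4.0 / ((d + 2) * n_class)) ** (1.0 / (d + 4))


def smoothed_bootstrap_rebalance(
    features: np.ndarray,
    labels: np.ndarray,
    p: float = 0.5,
    n_out: int | None = None,
    kernel_shrink: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a rebalanced smoothed-bootstrap sample.

    Each output row picks class 1 with probability ``p``, a seed row uniformly
    within that class, and adds Gaussian noise with the per-feature,
    per-class kernel bandwidth; ``kernel_shrink=0`` degenerates to a plain
    class-rebalancing bootstrap.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    n_out = len(y) if n_out is None else n_out
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    rng = np.random.default_rng(seed)
    d = X.shape[1]

    rows_by_class = {c: np.flatnonzero(y == c) for c in classes}
    h_by_class = {}
    for c, rows in rows_by_class.items():
        if len(rows) == 1 and kernel_shrink > 0:
            warnings.warn(f"class {c} has a single member; using pooled bandwidth", stacklevel=2)
            sigma = X.std(axis=0, ddof=1)
        else:
            sigma = X[rows].std(axis=0, ddof=1) if len(rows) > 1 else X.std(axis=0, ddof=1)
        h_by_class[c] = _rose_bandwidth(sigma, max(len(rows), 2), d, kernel_shrink)

    pos = classes.max()
    draw_pos = rng.random(n_out) < p
    out_y = np.where(draw_pos, pos, classes.min())
    out_X = np.empty((n_out, d))
    for c in classes:
        sel = np.flatnonzero(out_y == c)
        src = rng.choice(rows_by_class[c], size=len(sel), replace=True)
        noise = rng.standard_normal((len(sel), d)) * h_by_class[c] if kernel_shrink > 0 else 0.0
        out_X[sel] = X[src] + noise
    return out_X, out_y


# ---------------------------------------------------------------------------
# L1 logistic path with sequential strong-rule screening


def _logistic_lasso_path(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, tol: float = 1e-5, max_screen_rounds: int = 10
) -> np.ndarray:
    """Coefficients along a decreasing L1 path.

    Penalty parameterization: minimize (1/n) * logistic deviance/2 + lam *
    ||beta||_1, i.e. sklearn's C = 1 / (n * lam).  Columns are screened per
    lambda with the sequential strong rule and the KKT conditions are checked
    on the excluded set, so the result matches a full-matrix fit.
    """
    n, p = X.shape
    betas = np.zeros((len(lambdas), p))
    ybar = y.mean()
    prob = np.full(n, ybar)
    prev_lam = lambdas[0]
    active = np.zeros(p, dtype=bool)
    for k, lam in enumerate(lambdas):
        grad = np.abs(X.T @ (y - prob)) / n
        cand = active | (grad >= 2.0 * lam - prev_lam)
        beta = np.zeros(p)
        for _ in range(max_screen_rounds):
            idx = np.flatnonzero(cand)
            if idx.size:
                clf = LogisticRegression(
                    l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear", max_iter=1000,
                    tol=tol, random_state=0,
                )
                clf.fit(X[:, idx], y)
                beta = np.zeros(p)
                beta[idx] = clf.coef_[0]
                eta = X[:, idx] @ clf.coef_[0] + clf.intercept_[0]
            else:
                eta = np.full(n, np.log(ybar / (1 - ybar)) if 0 < ybar < 1 else 0.0)
            prob = 1.0 / (1.0 + np.exp(-eta))
            viol = (~cand) & (np.abs(X.T @ (y - prob)) / n > lam * (1 + 1e-3))
            if not viol.any():
                break
            cand |= viol
        betas[k] = beta
        active = beta != 0
        prev_lam = lam
    return betas


def _logistic_deviance(X: np.ndarray, y: np.ndarray, betas: np.ndarray, intercept_from_train: float) -> np.ndarray:
    """Mean binomial deviance of each path point on held-out data.

    The intercept is refit per path point implicitly via the training fit; we
    approximate the held-out linear predictor with the training intercept of
    the base rate (adequate for model comparison across lambdas)."""
    eta = X @ betas.T + intercept_from_train
    eta = np.clip(eta, -30, 30)
    ll = y[:, None] * eta - np.log1p(np.exp(eta))
    return -2.0 * ll.mean(axis=0)


@dataclass
class SelectionConfig:
    n_iterations: int = 200
    subsample_fraction: float = 0.8
    cv_folds: int = 5
    cv_repeats: int = 3
    lambda_grid: np.ndarray | None = None
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    rebalance_p: float = 0.5
    rebalance_size: int | None = None  # None: same size as the subsample
    kernel_shrink: float = 1.0
    model: str = "logistic"  # or "cox"
    max_retries: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if g.size == 0 or (g <= 0).any() or not (np.diff(g) <= 0).all():
                raise ValueError("lambda_grid must be nonempty, positive and sorted descending")
        if self.model not in ("logistic", "cox"):
            raise ValueError("model must be 'logistic' or 'cox'")


@dataclass
class SelectionScoreTable:
    """Per-assay stability score: sum over iterations of |beta| at the
    CV-optimal penalty, plus the count of iterations selecting the assay."""

    table: pd.DataFrame  # index assay_id, columns: score, times_selected
    n_iterations: int

    def __post_init__(self) -> None:
        t = self.table
        if (t["score"] < 0).any():
            raise ValueError("scores must be nonnegative")
        if (t["times_selected"] > self.n_iterations).any():
            raise ValueError("times_selected exceeds n_iterations")
        if ((t["score"] == 0) & (t["times_selected"] > 0)).any():
            raise ValueError("zero score with positive selection count")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="assay_id")


def _lambda_grid_for(X: np.ndarray, y: np.ndarray, cfg: SelectionConfig) -> np.ndarray:
    if cfg.lambda_grid is not None:
        return np.asarray(cfg.lambda_grid, dtype=float)
    lam_max = np.abs(X.T @ (y - y.mean())).max() / len(y)
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambda)


def _one_selection_iteration(
    X: np.ndarray, y: np.ndarray, cfg: SelectionConfig, seed: int
) -> np.ndarray:
    """Subsample, rebalance, standardize, CV-tune lambda, refit; returns |beta|."""
    rng = np.random.default_rng(seed)
    n = len(y)
    for _ in range(cfg.max_retries):
        take = rng.choice(n, size=max(2, int(round(cfg.subsample_fraction * n))), replace=False)
        if len(np.unique(y[take])) == 2:
            break
    else:
        raise RuntimeError("could not draw a subsample containing both classes")
    n_out = cfg.rebalance_size or len(take)
    Xb, yb = smoothed_bootstrap_rebalance(
        X[take], y[take], p=cfg.rebalance_p, n_out=n_out,
        kernel_shrink=cfg.kernel_shrink, seed=int(rng.integers(2**31)),
    )
    mu, sd = Xb.mean(axis=0), Xb.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xb - mu) / sd

    grid = _lambda_grid_for(Xs, yb, cfg)
    dev = np.zeros(len(grid))
    n_splits = 0
    for rep in range(cfg.cv_repeats):
        skf = StratifiedKFold(cfg.cv_folds, shuffle=True, random_state=int(rng.integers(2**31)))
        for train, test in skf.split(Xs, yb):
            betas = _logistic_lasso_path(Xs[train], yb[train], grid)
            ybar = yb[train].mean()
            icpt = np.log(ybar / (1 - ybar))
            dev += _logistic_deviance(Xs[test], yb[test], betas, icpt)
            n_splits += 1
    lam_opt = grid[int(np.argmin(dev / n_splits))]
    path = _logistic_lasso_path(Xs, yb, grid[grid >= lam_opt])
    return np.abs(path[-1])


def _one_cox_iteration(X, times, events, cfg: SelectionConfig, seed: int) -> np.ndarray:
    """Cox variant: L1 Cox path on the raw subsample (no rebalancing)."""
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    rng = np.random.default_rng(seed)
    n = len(times)
    for _ in range(cfg.max_retries):
        take = rng.choice(n, size=max(2, int(round(cfg.subsample_fraction * n))), replace=False)
        if events[take].sum() >= cfg.cv_folds:
            break
    else:
        raise RuntimeError("could not draw a subsample with enough events")
    Xs = X[take]
    mu, sd = Xs.mean(axis=0), Xs.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xs - mu) / sd
    y = Surv.from_arrays(events[take].astype(bool), times[take])
    net = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=cfg.n_lambda, alpha_min_ratio=cfg.lambda_min_ratio, normalize=False
    )
    net.fit(Xs, y)
    from .risk import _cox_cv_best_alpha  # shared CV helper

    alpha = _cox_cv_best_alpha(Xs, times[take], events[take], np.asarray(net.alphas_),
                               cv_folds=cfg.cv_folds, seed=int(rng.integers(2**31)))
    k = int(np.argmin(np.abs(np.asarray(net.alphas_) - alpha)))
    return np.abs(net.coef_[:, k])


def subsampled_selection(
    features: ProteinMatrix | pd.DataFrame,
    outcomes: OutcomeTable,
    config: SelectionConfig | None = None,
) -> SelectionScoreTable:
    """Aggregate selection scores over repeated subsampled L1 fits.

    ``features`` rows are aligned to ``outcomes`` by sample id; only samples
    with an unambiguous binary label at the horizon enter the logistic
    variant.
    """
    cfg = config or SelectionConfig()
    cfg.validate()
    frame = features.values if isinstance(features, ProteinMatrix) else features
    assay_ids = frame.columns

    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_iterations)
    score = np.zeros(len(assay_ids))
    times_selected = np.zeros(len(assay_ids), dtype=int)

    if cfg.model == "logistic":
        labels = binary_label_at_horizon(outcomes)
        ids = labels.index.intersection(frame.index)
        X = frame.loc[ids].to_numpy(dtype=float)
        y = labels.loc[ids].to_numpy()
        if len(np.unique(y)) < 2:
            raise ValueError("selection set must contain cases and controls")
        for i in range(cfg.n_iterations):
            beta_abs = _one_selection_iteration(X, y, cfg, int(seeds[i]))
            score += beta_abs
            times_selected += beta_abs > 0
    else:
        ids = outcomes.sample_ids.intersection(frame.index)
        X = frame.loc[ids].to_numpy(dtype=float)
        t = outcomes.table.loc[ids]
        for i in range(cfg.n_iterations):
            beta_abs = _one_cox_iteration(
                X, t["time_years"].to_numpy(), t["event"].to_numpy(), cfg, int(seeds[i])
            )
            score += beta_abs
            times_selected += beta_abs > 0

    table = pd.DataFrame({"score": score, "times_selected": times_selected}, index=assay_ids)
    return SelectionScoreTable(table, cfg.n_iterations)


# ---------------------------------------------------------------------------
# ranking


def rank_top_k(scores: SelectionScoreTable, k: int) -> list[str]:
    """The k assays with the largest selection score, descending; ties broken
    by lexicographic assay id; zero-score assays are never returned."""
    if k < 1:
        raise ValueError("k must be >= 1")
    t = scores.table[scores.table["score"] > 0]
    if k > len(t):
        warnings.warn(f"only {len(t)} assays have positive scores; returning all", stacklevel=2)
        k = len(t)
    order = np.lexsort((t.index.to_numpy(), -t["score"].to_numpy()))
    return list(t.index[order][:k])


def sparsify_by_weight_product(optimized_model, scores: SelectionScoreTable, k: int) -> list[str]:
    """Rank penalized model features by |optimized weight| x selection score
    and return the top k.  Unpenalized (clinical) features are not ranked —
    they are always retained downstream."""
    if k < 1:
        raise ValueError("k must be >= 1")
    products = {}
    for name, beta, penalized in zip(
        optimized_model.feature_names, optimized_model.beta, optimized_model.penalized
    ):
        if not penalized:
            continue
        if name not in scores.table.index:
            raise KeyError(f"feature {name!r} missing from the selection score table")
        products[name] = abs(float(beta)) * float(scores.table.loc[name, "score"])
    ranked = sorted(products, key=lambda a: (-products[a], a))
    return ranked[:k]
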