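"""Regularized Cox risk models: the clinical benchmark and protein-augmented
variants, with Breslow baselines, absolute-risk prediction at the analysis
horizon, JSON serialization for frozen-weight transfer to external cohorts,
and the full model suite (clinical; clinical + top-5/10/20 proteins;
proteins-only top-5).

Coefficients are fit on standardized features by L1-penalized Cox partial
likelihood; the penalty applies only to features marked in ``penalized``
(clinical covariates in augmented models stay unpenalized so proteins cannot
displace the benchmark).  The penalty is tuned on a grid by k-fold
cross-validated held-out partial log-likelihood.  Ties are handled by the
Breslow approximation throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .cohort import ClinicalCovariates, OutcomeTable, ProteinMatrix
from .selection import SelectionScoreTable, SplitScheme, rank_top_k, sparsify_by_weight_product

__all__ = ["FittedRiskModel", "ModelSuite", "fit_penalized_cox", "predict_risk", "fit_model_suite"]


def breslow_cumhaz(linear_predictor: np.ndarray, times: np.ndarray, events: np.ndarray, at: float) -> float:
    """Breslow cumulative baseline hazard evaluated at time ``at``."""
    order = np.argsort(times, kind="stable")
    t, e, lp = times[order], events[order], linear_predictor[order]
    shift = lp.max()  # overflow guard; cancels in the ratio below
    risk = np.exp(lp - shift)
    # cumulative risk-set sums from the right
    rev_cum = np.cumsum(risk[::-1])[::-1]
    h0 = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = e[i:j].sum()
        if d > 0 and t[i] <= at:
            h0 += d / (rev_cum[i] * np.exp(shift))
        i = j
    return float(h0)


def cox_partial_loglik(linear_predictor: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Breslow-tie Cox partial log-likelihood."""
    order = np.argsort(times, kind="stable")
    t, e, lp = times[order], events[order], linear_predictor[order]
    shift = lp.max()  # overflow guard: log sum exp(lp) = shift + log sum exp(lp - shift)
    rev_cum = np.cumsum(np.exp(lp - shift)[::-1])[::-1]
    ll = 0.0
    i, n = 0, len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d_lp = lp[i:j][e[i:j] == 1]
        if d_lp.size:
            ll += d_lp.sum() - d_lp.size * (shift + np.log(rev_cum[i]))
        i = j
    return float(ll)


@dataclass
class FittedRiskModel:
    """A penalized Cox model frozen for prediction and transfer.

    Stores the feature list, coefficients (on the standardized scale), the
    standardization parameters captured at fit time, the tuned penalty, the
    Breslow cumulative baseline hazard at the horizon, and the penalty mask.
    """

    feature_names: list[str]
    beta: np.ndarray
    lambda_opt: float
    center: np.ndarray
    scale: np.ndarray
    baseline_cumhaz: float
    horizon_years: float
    penalized: np.ndarray = field(default=None)  # bool per feature

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.penalized is None:
            self.penalized = np.ones(len(self.beta), dtype=bool)
        self.penalized = np.asarray(self.penalized, dtype=bool)
        if len(self.feature_names) != len(self.beta):
            raise ValueError("feature_names and beta must align")
        if self.baseline_cumhaz < 0:
            raise ValueError("baseline_cumhaz must be nonnegative")

    # -- serialization (frozen-weight transfer) -----------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_names": self.feature_names,
            "beta": self.beta.tolist(),
            "lambda_opt": self.lambda_opt,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "baseline_cumhaz": self.baseline_cumhaz,
            "horizon_years": self.horizon_years,
            "penalized": self.penalized.astype(int).tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedRiskModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            feature_names=d["feature_names"],
            beta=np.array(d["beta"]),
            lambda_opt=d["lambda_opt"],
            center=np.array(d["center"]),
            scale=np.array(d["scale"]),
            baseline_cumhaz=d["baseline_cumhaz"],
            horizon_years=d["horizon_years"],
            penalized=np.array(d["penalized"], dtype=bool),
        )


def _standardize(F: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = F.mean(axis=0)
    sd = F.std(axis=0)
    sd[sd == 0] = 1.0
    return (F - mu) / sd, mu, sd


def _fit_coxnet_path(X, y, alphas: np.ndarray, penalty_factor=None):
    """Fit a Coxnet L1 path, truncating the small-alpha tail if the
    coordinate descent diverges (possible when unpenalized covariates are
    present); returns (model, fitted alpha array)."""
    grid = np.asarray(alphas, dtype=float)
    while len(grid) >= 1:
        net = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=list(grid), penalty_factor=penalty_factor,
            normalize=False, max_iter=100000,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net.fit(X, y)
            return net, np.asarray(net.alphas_)
        except ArithmeticError:
            grid = grid[:-max(1, len(grid) // 5)]
    raise ArithmeticError("Cox path diverged at every requested penalty")


def _cox_cv_best_alpha(
    X: np.ndarray, times: np.ndarray, events: np.ndarray, alphas: np.ndarray,
    cv_folds: int = 5, seed: int = 0, penalty_factor: np.ndarray | None = None,
) -> float:
    """Pick the alpha maximizing the cross-validated partial log-likelihood.

    Verweij–Van Houwelingen form: each fold contributes
    pl(all data; beta_train) - pl(train; beta_train), which keeps full risk
    sets and is much less noisy than scoring the small test fold directly.
    """
    skf = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
    ll = np.zeros(len(alphas))
    for train, test in skf.split(X, events):
        if events[train].sum() == 0 or events[test].sum() == 0:
            continue
        y = Surv.from_arrays(events[train].astype(bool), times[train])
        net, fitted_alphas = _fit_coxnet_path(X[train], y, alphas, penalty_factor)
        for k, a in enumerate(alphas):
            kk = int(np.argmin(np.abs(fitted_alphas - a)))
            beta = net.coef_[:, kk]
            ll[k] += cox_partial_loglik(X @ beta, times, events) - cox_partial_loglik(
                X[train] @ beta, times[train], events[train]
            )
    return float(alphas[int(np.argmax(ll))])


def fit_penalized_cox(
    features: pd.DataFrame,
    outcomes: OutcomeTable,
    cv_folds: int = 5,
    lambda_grid: np.ndarray | None = None,
    penalized_mask: np.ndarray | None = None,
    seed: int = 0,
    n_lambda: int = 30,
    lambda_min_ratio: float = 1e-3,
) -> FittedRiskModel:
    """L1-penalized Cox fit with cross-validated penalty.

    ``penalized_mask`` marks which coefficients the L1 penalty applies to
    (True everywhere by default); a grid of ``[0.0]`` requests an unpenalized
    Breslow Cox fit.
    """
    ids = features.index.intersection(outcomes.sample_ids)
    F = features.loc[ids].to_numpy(dtype=float)
    t = outcomes.table.loc[ids]
    times = t["time_years"].to_numpy(dtype=float)
    events = t["event"].to_numpy(dtype=int)
    if events.sum() == 0:
        raise ValueError("no events in the training data")
    if events.sum() < cv_folds:
        raise ValueError("fewer events than CV folds")
    if lambda_grid is not None and len(np.asarray(lambda_grid)) == 0:
        raise ValueError("lambda grid is empty")

    Xs, mu, sd = _standardize(F)
    names = list(features.columns)
    mask = np.ones(len(names), dtype=bool) if penalized_mask is None else np.asarray(penalized_mask, bool)
    y = Surv.from_arrays(events.astype(bool), times)

    grid = None if lambda_grid is None else np.sort(np.asarray(lambda_grid, float))[::-1]
    if grid is not None and np.allclose(grid, 0.0):
        cph = CoxPHSurvivalAnalysis(ties="breslow", n_iter=200, tol=1e-10)
        cph.fit(Xs, y)
        beta = cph.coef_.copy()
        lam_opt = 0.0
    else:
        pf = mask.astype(float)
        if not pf.any():
            # nothing penalized: the penalty is inert, fit unpenalized
            cph = CoxPHSurvivalAnalysis(ties="breslow", n_iter=200, tol=1e-10)
            cph.fit(Xs, y)
            beta = cph.coef_.copy()
            lam_opt = 0.0
        else:
            if grid is None:
                ratio = lambda_min_ratio
                while True:
                    try:
                        probe = CoxnetSurvivalAnalysis(
                            l1_ratio=1.0, n_alphas=n_lambda, alpha_min_ratio=ratio,
                            penalty_factor=pf, normalize=False,
                        )
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            probe.fit(Xs, y)
                        break
                    except ArithmeticError:
                        ratio *= 10.0
                        if ratio >= 1.0:
                            raise
                grid = np.asarray(probe.alphas_)
            lam_opt = _cox_cv_best_alpha(Xs, times, events, grid, cv_folds, seed, pf)
            net, fitted = _fit_coxnet_path(Xs, y, grid[grid >= lam_opt], pf)
            k = int(np.argmin(np.abs(fitted - lam_opt)))
            beta = net.coef_[:, k].copy()

    lp = Xs @ beta
    h0 = breslow_cumhaz(lp, times, events, outcomes.horizon_years)
    return FittedRiskModel(
        feature_names=names, beta=beta, lambda_opt=float(lam_opt), center=mu, scale=sd,
        baseline_cumhaz=h0, horizon_years=outcomes.horizon_years, penalized=mask,
    )


def predict_risk(model: FittedRiskModel, features: pd.DataFrame) -> pd.DataFrame:
    """Linear predictor (standardized scale) and absolute risk at the horizon,
    1 - exp(-H0 * exp(lp)), per sample."""
    missing = [f for f in model.feature_names if f not in features.columns]
    if missing:
        raise KeyError(f"missing model feature(s): {missing}")
    X = features[model.feature_names].to_numpy(dtype=float)
    lp = (X - model.center) / model.scale @ model.beta
    risk = 1.0 - np.exp(-model.baseline_cumhaz * np.exp(lp))
    return pd.DataFrame({"linear_predictor": lp, "absolute_risk": risk}, index=features.index)


# ---------------------------------------------------------------------------
# model suite


@dataclass
class ModelSuite:
    """The benchmark and augmented models fit on a shared training split."""

    members: dict[str, FittedRiskModel]
    horizon_years: float
    split_rule: str
    validation_c: dict[str, float] = field(default_factory=dict)
    best_protein_model: str | None = None

    def __getitem__(self, key: str) -> FittedRiskModel:
        return self.members[key]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, model in self.members.items():
            model.to_json(out / f"{name}.json")
        meta = {
            "horizon_years": self.horizon_years,
            "split_rule": self.split_rule,
            "validation_c": self.validation_c,
            "best_protein_model": self.best_protein_model,
        }
        (out / "suite.json").write_text(json.dumps(meta, indent=1))


def fit_model_suite(
    matrix: ProteinMatrix,
    covariates: ClinicalCovariates,
    outcomes: OutcomeTable,
    splits: SplitScheme,
    scores: SelectionScoreTable,
    cv_folds: int = 5,
    seed: int = 0,
    assay_features: pd.DataFrame | None = None,
    top_k_grid: tuple[int, ...] = (20, 10, 5),
) -> ModelSuite:
    """Fit the full suite on the training split.

    Members: ``clinical`` (all covariates penalized, the benchmark),
    ``clinical_proteins_{20,10,5}`` (clinical unpenalized + penalized
    proteins), ``proteins_only_5``, and ``clinical_assays`` when an assay
    frame is supplied.  Validation C-indices (point estimates) are recorded
    and the best clinical+proteins member is marked.
    """
    from .evaluation import harrell_c

    clin = covariates.design_matrix()
    proteins = matrix.values
    train_ids = splits.training_ids.intersection(outcomes.sample_ids)
    val_ids = splits.validation_ids.intersection(outcomes.sample_ids)
    train_out = outcomes.subset(train_ids)

    members: dict[str, FittedRiskModel] = {}
    members["clinical"] = fit_penalized_cox(
        clin.loc[train_ids], train_out, cv_folds=cv_folds, seed=seed
    )

    top20 = rank_top_k(scores, max(top_k_grid))
    feats20 = pd.concat([clin, proteins[top20]], axis=1)
    mask20 = np.array([f in top20 for f in feats20.columns])
    members[f"clinical_proteins_{max(top_k_grid)}"] = fit_penalized_cox(
        feats20.loc[train_ids], train_out, cv_folds=cv_folds, penalized_mask=mask20, seed=seed
    )

    for k in sorted(set(top_k_grid) - {max(top_k_grid)}, reverse=True):
        top_k = sparsify_by_weight_product(members[f"clinical_proteins_{max(top_k_grid)}"], scores, k)
        feats = pd.concat([clin, proteins[top_k]], axis=1)
        mask = np.array([f in top_k for f in feats.columns])
        members[f"clinical_proteins_{k}"] = fit_penalized_cox(
            feats.loc[train_ids], train_out, cv_folds=cv_folds, penalized_mask=mask, seed=seed
        )
        if k == 5:
            members["proteins_only_5"] = fit_penalized_cox(
                proteins[top_k].loc[train_ids], train_out, cv_folds=cv_folds, seed=seed
            )

    if assay_features is not None:
        feats = pd.concat([clin, assay_features], axis=1)
        mask = np.array([f in assay_features.columns for f in feats.columns])
        members["clinical_assays"] = fit_penalized_cox(
            feats.loc[train_ids], train_out, cv_folds=cv_folds, penalized_mask=mask, seed=seed
        )

    all_features = pd.concat([clin, proteins, assay_features], axis=1) if assay_features is not None else pd.concat([clin, proteins], axis=1)
    val_out = outcomes.subset(val_ids)
    validation_c = {}
    for name, model in members.items():
        pred = predict_risk(model, all_features.loc[val_ids])
        validation_c[name] = harrell_c(
            val_out.table["time_years"].to_numpy(),
            val_out.table["event"].to_numpy(),
            pred["linear_predictor"].to_numpy(),
        )
    protein_members = [f"clinical_proteins_{k}" for k in top_k_grid if f"clinical_proteins_{k}" in members]
    best = max(protein_members, key=lambda m: validation_c[m])
    return ModelSuite(members, outcomes.horizon_years, splits.rule, validation_c, best)
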