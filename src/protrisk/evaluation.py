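"""Validation machinery for risk models.

Harrell's concordance over paired bootstrap resamples, delta-C significance
by the CI-excludes-zero rule, screening curves (detection rate, false
positive rate, positive likelihood ratio over an FPR grid), post-test
probability, category-free net reclassification with a risk-difference
margin, integrated discrimination improvement, stratified and
alternate-horizon evaluation, and case downsampling.

Concordance definition: a pair is comparable iff the earlier time is an
event; tied risk scores count 1/2; pairs with equal times are not comparable.
For bootstrap speed, resampling is expressed through multiplicity weights w
and C(w) = (w' K w) / (w' M w), with M the comparability matrix and K the
concordance-scored matrix — exactly the plug-in concordance of the resampled
data (self-pairs are impossible since M has a zero diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import OutcomeTable

__all__ = [
    "harrell_c",
    "BootstrapCResult",
    "DeltaCResult",
    "bootstrap_compare",
    "ScreeningCurve",
    "screening_curve",
    "post_test_probability",
    "ReclassResult",
    "category_free_nri",
    "idi",
    "stratified_eval",
    "downsample_cases",
    "case_control_status",
]

DEFAULT_FPR_GRID = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40)


def _pair_matrices(times: np.ndarray, events: np.ndarray, scores: np.ndarray):
    """Comparability matrix M (i comparable with j: t_i < t_j and e_i = 1)
    and concordance score matrix K (1 concordant, 0.5 tie)."""
    t = times[:, None]
    comp = (t < times[None, :]) & (events[:, None] == 1)
    s = scores[:, None]
    conc = np.where(s > scores[None, :], 1.0, np.where(s == scores[None, :], 0.5, 0.0))
    return comp, conc * comp


def harrell_c(times, events, scores) -> float:
    """Harrell's concordance index in [0, 1]."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    scores = np.asarray(scores, float)
    if not (len(times) == len(events) == len(scores)):
        raise ValueError("times, events, scores must have equal length")
    if events.sum() < 1:
        raise ValueError("need at least one event")
    comp, conc = _pair_matrices(times, events, scores)
    n_comp = comp.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    return float(conc.sum() / n_comp)


@dataclass
class BootstrapCResult:
    c_mean: float
    c_distribution: np.ndarray
    B: int
    seed: int

    def __post_init__(self) -> None:
        self.c_distribution = np.asarray(self.c_distribution, float)
        if len(self.c_distribution) != self.B:
            raise ValueError("distribution length must equal B")
        if ((self.c_distribution < 0) | (self.c_distribution > 1)).any():
            raise ValueError("concordances must lie in [0, 1]")


@dataclass
class DeltaCResult:
    delta_mean: float
    ci_low: float
    ci_high: float

    @property
    def significant(self) -> bool:
        """True iff the 95% CI of the paired bootstrap differences excludes 0."""
        return self.ci_low > 0.0 or self.ci_high < 0.0

    @property
    def significant_improvement(self) -> bool:
        """Directional version: the whole CI lies above zero."""
        return self.ci_low > 0.0


def bootstrap_compare(
    scores_a, scores_b, outcomes: OutcomeTable, B: int = 1000, seed: int = 0
) -> tuple[BootstrapCResult, BootstrapCResult, DeltaCResult]:
    """Paired bootstrap C-index comparison of two risk scores on the same
    samples; delta = C_B - C_A per replicate; CI = empirical 2.5/97.5
    percentiles.  Replicates without events or comparable pairs are redrawn.
    """
    t = outcomes.table
    times = t["time_years"].to_numpy(float)
    events = t["event"].to_numpy(int)
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    n = len(times)
    comp, conc_a = _pair_matrices(times, events, a)
    _, conc_b = _pair_matrices(times, events, b)
    compf = comp.astype(float)

    rng = np.random.default_rng(seed)
    c_a = np.empty(B)
    c_b = np.empty(B)
    for r in range(B):
        for _ in range(100):
            w = rng.multinomial(n, np.full(n, 1.0 / n)).astype(float)
            denom = w @ compf @ w
            if denom > 0:
                break
        else:
            raise RuntimeError("could not draw a bootstrap replicate with comparable pairs")
        c_a[r] = (w @ conc_a @ w) / denom
        c_b[r] = (w @ conc_b @ w) / denom
    delta = c_b - c_a
    lo, hi = np.percentile(delta, (2.5, 97.5))
    return (
        BootstrapCResult(float(c_a.mean()), c_a, B, seed),
        BootstrapCResult(float(c_b.mean()), c_b, B, seed),
        DeltaCResult(float(delta.mean()), float(lo), float(hi)),
    )


# ---------------------------------------------------------------------------
# screening metrics


def case_control_status(outcomes: OutcomeTable, horizon: float | None = None) -> pd.Series:
    """1 = case (incident event within horizon), 0 = control (event-free with
    follow-up >= horizon); early-censored non-events are excluded."""
    horizon = outcomes.horizon_years if horizon is None else horizon
    t = outcomes.table
    case = (t["event"] == 1) & (t["time_years"] <= horizon)
    control = (t["event"] == 0) & (t["time_years"] >= horizon)
    return pd.Series(np.where(case, 1, 0), index=t.index)[case | control]


@dataclass
class ScreeningCurve:
    """Per-FPR-target confusion counts with DR and LR.

    ``table`` columns: target_fpr, threshold, TP, FP, TN, FN, fpr, dr, lr —
    fpr/dr/lr are the realized values (fpr = FP/(FP+TN), dr = TP/(TP+FN),
    lr = dr/fpr exactly)."""

    table: pd.DataFrame

    def at_fpr(self, target: float) -> pd.Series:
        row = self.table[np.isclose(self.table["target_fpr"], target)]
        if row.empty:
            raise KeyError(f"target FPR {target} not on the grid")
        return row.iloc[0]


def screening_curve(
    scores,
    outcomes: OutcomeTable,
    horizon: float | None = None,
    fpr_grid=DEFAULT_FPR_GRID,
) -> ScreeningCurve:
    """DR/FPR/LR at thresholds set on control-score quantiles.

    At target FPR f, the threshold is the (k+1)-th largest control score with
    k = floor(f * n_controls), so exactly k controls score strictly above it
    when control scores are distinct; realized counts are reported alongside
    the target.
    """
    status = case_control_status(outcomes, horizon)
    s = pd.Series(np.asarray(scores, float), index=outcomes.table.index).loc[status.index]
    cases = s[status == 1].to_numpy()
    controls = s[status == 0].to_numpy()
    if len(controls) < 10:
        raise ValueError("fewer than 10 controls")
    if len(cases) == 0:
        raise ValueError("no cases at the horizon")
    ctrl_sorted = np.sort(controls)
    rows = []
    for f in fpr_grid:
        k = int(np.floor(f * len(controls) + 1e-9))
        thr = ctrl_sorted[len(controls) - k - 1] if k < len(controls) else -np.inf
        tp = int((cases > thr).sum())
        fp = int((controls > thr).sum())
        fn = len(cases) - tp
        tn = len(controls) - fp
        fpr = fp / (fp + tn)
        dr = tp / (tp + fn)
        rows.append(
            {
                "target_fpr": f,
                "threshold": thr,
                "TP": tp,
                "FP": fp,
                "TN": tn,
                "FN": fn,
                "fpr": fpr,
                "dr": dr,
                "lr": dr / fpr if fpr > 0 else np.inf,
            }
        )
    return ScreeningCurve(pd.DataFrame(rows))


def post_test_probability(lr: float, pretest: float) -> float:
    """Posterior disease probability from a positive likelihood ratio:
    post-odds = LR x pre-odds."""
    if lr < 0:
        raise ValueError("lr must be nonnegative")
    if not 0.0 <= pretest < 1.0:
        raise ValueError("pretest probability must lie in [0, 1)")
    odds = pretest / (1.0 - pretest)
    return lr * odds / (1.0 + lr * odds)


# ---------------------------------------------------------------------------
# reclassification


@dataclass
class ReclassResult:
    cnri: float
    margin: float
    idi: float
    horizon_years: float

    def __post_init__(self) -> None:
        if not -2.0 <= self.cnri <= 2.0:
            raise ValueError("cNRI out of range")
        if not -1.0 <= self.idi <= 1.0:
            raise ValueError("IDI out of range")


def _case_control_risks(risk_old, risk_new, outcomes, horizon):
    status = case_control_status(outcomes, horizon)
    old = pd.Series(np.asarray(risk_old, float), index=outcomes.table.index).loc[status.index]
    new = pd.Series(np.asarray(risk_new, float), index=outcomes.table.index).loc[status.index]
    if ((old < 0) | (old > 1) | (new < 0) | (new > 1)).any():
        raise ValueError("risks must lie on the absolute-risk scale [0, 1]")
    is_case = (status == 1).to_numpy()
    if is_case.all() or not is_case.any():
        raise ValueError("need both cases and controls at the horizon")
    return old.to_numpy(), new.to_numpy(), is_case


def category_free_nri(
    risk_old, risk_new, outcomes: OutcomeTable, horizon: float | None = None, margin: float = 0.15
) -> float:
    """Category-free NRI with a risk-difference margin: a move counts only if
    |risk_new - risk_old| exceeds the margin."""
    old, new, is_case = _case_control_risks(risk_old, risk_new, outcomes, horizon)
    up = (new - old) > margin
    down = (old - new) > margin
    case_part = up[is_case].mean() - down[is_case].mean()
    control_part = down[~is_case].mean() - up[~is_case].mean()
    return float(case_part + control_part)


def idi(risk_old, risk_new, outcomes: OutcomeTable, horizon: float | None = None) -> float:
    """Integrated discrimination improvement: gain in discrimination slope."""
    old, new, is_case = _case_control_risks(risk_old, risk_new, outcomes, horizon)
    slope_new = new[is_case].mean() - new[~is_case].mean()
    slope_old = old[is_case].mean() - old[~is_case].mean()
    return float(slope_new - slope_old)


def reclassification(
    risk_old, risk_new, outcomes: OutcomeTable, horizon: float | None = None, margin: float = 0.15
) -> ReclassResult:
    h = outcomes.horizon_years if horizon is None else horizon
    return ReclassResult(
        cnri=category_free_nri(risk_old, risk_new, outcomes, horizon, margin),
        margin=margin,
        idi=idi(risk_old, risk_new, outcomes, horizon),
        horizon_years=h,
    )


# ---------------------------------------------------------------------------
# stratified evaluation and downsampling


def stratified_eval(
    scores_a,
    scores_b,
    outcomes: OutcomeTable,
    strata: pd.Series,
    min_cases: int = 20,
    B: int = 1000,
    seed: int = 0,
) -> dict[str, dict]:
    """Per-stratum paired bootstrap comparison; strata with fewer than
    ``min_cases`` incident cases are reported as skipped."""
    t = outcomes.table
    if not strata.index.equals(t.index):
        strata = strata.loc[t.index]
    a = pd.Series(np.asarray(scores_a, float), index=t.index)
    b = pd.Series(np.asarray(scores_b, float), index=t.index)
    results: dict[str, dict] = {}
    any_evaluated = False
    for level in pd.unique(strata):
        ids = t.index[strata == level]
        n_cases = int(t.loc[ids, "event"].sum())
        if n_cases < min_cases:
            results[str(level)] = {"skipped": True, "reason": f"{n_cases} cases < {min_cases}"}
            continue
        sub = OutcomeTable(t.loc[ids], outcomes.horizon_years)
        ra, rb, delta = bootstrap_compare(a.loc[ids], b.loc[ids], sub, B=B, seed=seed)
        results[str(level)] = {
            "skipped": False,
            "c_a": ra.c_mean,
            "c_b": rb.c_mean,
            "delta": delta,
        }
        any_evaluated = True
    if not any_evaluated:
        raise ValueError("all strata skipped: no stratum reaches the case floor")
    return results


def downsample_cases(outcomes: OutcomeTable, target_cases: int, seed: int = 0) -> OutcomeTable:
    """Keep a uniform random subset of cases of the target size plus all
    non-cases (the case-downsampling sensitivity design)."""
    t = outcomes.table
    case_ids = t.index[t["event"] == 1]
    if target_cases > len(case_ids):
        raise ValueError(f"target_cases {target_cases} exceeds available cases {len(case_ids)}")
    rng = np.random.default_rng(seed)
    keep_cases = case_ids[np.sort(rng.choice(len(case_ids), size=target_cases, replace=False))]
    keep = t.index[t["event"] == 0].union(keep_cases, sort=False)
    keep = t.index[t.index.isin(keep)]  # preserve original row order
    return OutcomeTable(t.loc[keep].copy(), outcomes.horizon_years)
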