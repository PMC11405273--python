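"""Synthetic proteomic survival cohorts with known sparse signal structure.

Emulates a biobank-style plasma-proteomics cohort: thousands of correlated
NPX-like assays grouped in panels, a handful of truly predictive proteins with
known log hazard ratios, basic clinical covariates with their own effects,
exponential (optionally Weibull) proportional-hazards event times under
administrative censoring at a fixed horizon, prevalent-case flags and
MCAR/plate-style missingness.  Ground truth is returned alongside the data so
every downstream stage (QC, imputation, selection, modelling, evaluation) can
be scored against the generating parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "ProteinMatrix",
    "ClinicalCovariates",
    "OutcomeTable",
    "SimulationTruth",
    "generate_cohort",
    "apply_incidence_filters",
    "inject_missingness",
]

ETHNICITIES = ("white", "asian", "black", "mixed", "other")
SMOKING = ("never", "previous", "current")
ALCOHOL = ("never", "occasional", "regular")


@dataclass
class CohortConfig:
    """Generating parameters for one synthetic cohort.

    ``causal_assays`` are 0-based assay column indices; ``beta_protein`` gives
    one log hazard ratio per causal assay (per 1 s.d. of NPX).
    ``beta_clinical`` holds log hazard ratios for the standardized clinical
    covariates (keys among age/sex/bmi/smoking).  ``baseline_rate`` is the
    exponential baseline hazard in events per person-year; if
    ``target_case_count`` is set it is recalibrated by bisection so the
    expected number of incident cases within the horizon matches the target.
    """

    n_samples: int = 4000
    n_assays: int = 600
    n_panels: int = 4
    block_size: int = 10
    block_rho: float = 0.3
    causal_assays: tuple[int, ...] = ()
    beta_protein: tuple[float, ...] = ()
    beta_clinical: dict[str, float] = field(
        default_factory=lambda: {"age": 0.35, "sex": 0.2, "bmi": 0.15, "smoking": 0.25}
    )
    baseline_rate: float = 0.005
    admin_censor_years: float = 10.0
    target_case_count: int | None = None
    missing_rate: float = 0.0
    prevalent_frac: float = 0.0
    dropout_rate: float = 0.0
    weibull_shape: float = 1.0
    family_history_assoc: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if self.n_assays % self.n_panels:
            raise ValueError("n_panels must divide n_assays")
        per_panel = self.n_assays // self.n_panels
        if per_panel % self.block_size:
            raise ValueError("block_size must divide the per-panel assay count")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must lie in [0, 1) for a positive-definite block")
        if len(self.causal_assays) != len(self.beta_protein):
            raise ValueError("causal_assays and beta_protein must have equal length")
        if any(not 0 <= j < self.n_assays for j in self.causal_assays):
            raise ValueError("causal assay index out of range")
        if len(set(self.causal_assays)) != len(self.causal_assays):
            raise ValueError("duplicate causal assay index")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.target_case_count is not None and self.target_case_count > self.n_samples:
            raise ValueError("target_case_count exceeds n_samples")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")


@dataclass
class ProteinMatrix:
    """Samples x assays NPX-like matrix with a panel map and a missingness mask.

    ``values`` always holds the underlying (complete) measurements; cells with
    ``missing_mask`` True are considered unobserved.  Keeping the masked truth
    allows imputation quality to be scored exactly.
    """

    values: pd.DataFrame
    panel_of: pd.Series
    missing_mask: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        if not self.values.columns.equals(self.missing_mask.columns) or not self.values.index.equals(
            self.missing_mask.index
        ):
            raise ValueError("values and missing_mask must be aligned")
        if not set(self.values.columns) <= set(self.panel_of.index):
            raise ValueError("every assay must map to exactly one panel")
        observed = self.values.to_numpy()[~self.missing_mask.to_numpy()]
        if not np.isfinite(observed).all():
            raise ValueError("observed values must be finite")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def assay_ids(self) -> pd.Index:
        return self.values.columns

    def observed(self) -> pd.DataFrame:
        """Values with masked cells replaced by NaN."""
        return self.values.mask(self.missing_mask)

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(self.values.copy(), self.panel_of.copy(), self.missing_mask.copy())

    def to_tsv(self, path: str | Path) -> None:
        """Write samples-in-rows TSV; masked cells are left empty."""
        self.observed().to_csv(path, sep="\t", na_rep="")


@dataclass
class ClinicalCovariates:
    """Per-sample clinical table: age, sex, BMI, ethnicity, smoking, alcohol,
    and a family-history flag for the configured disease."""

    table: pd.DataFrame

    REQUIRED = ("age", "sex", "bmi", "ethnicity", "smoking", "alcohol", "family_history")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing clinical columns: {missing}")
        if self.table[list(self.REQUIRED)].isna().any().any():
            raise ValueError("clinical covariates must have no missing values")

    def design_matrix(self, drop_family_history: bool = False) -> pd.DataFrame:
        """Numeric design matrix: continuous columns as-is, categoricals
        one-hot encoded with the first level as reference."""
        cols = {"age": self.table["age"].astype(float), "sex": self.table["sex"].astype(float), "bmi": self.table["bmi"].astype(float)}
        for cat, levels in (("ethnicity", ETHNICITIES), ("smoking", SMOKING), ("alcohol", ALCOHOL)):
            for level in levels[1:]:
                cols[f"{cat}_{level}"] = (self.table[cat] == level).astype(float)
        if not drop_family_history:
            cols["family_history"] = self.table["family_history"].astype(float)
        return pd.DataFrame(cols, index=self.table.index)


@dataclass
class OutcomeTable:
    """Per-sample time-to-event outcomes for one disease.

    ``time_years`` is follow-up time (0 for prevalent cases, which carry no
    incident time), ``event`` the incident-disease indicator within follow-up,
    ``prevalent`` the baseline-disease flag, ``horizon_years`` the analysis
    horizon."""

    table: pd.DataFrame
    horizon_years: float = 10.0

    def __post_init__(self) -> None:
        for col in ("time_years", "event", "prevalent"):
            if col not in self.table.columns:
                raise ValueError(f"outcome table missing column {col!r}")
        if (self.table["time_years"] < 0).any():
            raise ValueError("negative follow-up time")
        if not self.table["event"].isin((0, 1)).all() or not self.table["prevalent"].isin((0, 1)).all():
            raise ValueError("event and prevalent must be 0/1")
        if ((self.table["prevalent"] == 1) & (self.table["event"] == 1)).any():
            raise ValueError("prevalent cases carry no incident event")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_incident_cases(self) -> int:
        return int(self.table["event"].sum())

    def subset(self, ids) -> "OutcomeTable":
        return OutcomeTable(self.table.loc[ids], self.horizon_years)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="sample_id")


@dataclass
class SimulationTruth:
    """Generating parameters frozen at simulation time, for recovery scoring."""

    beta_true: pd.Series  # per assay, 0 off-support
    beta_clinical_true: dict[str, float]
    baseline_rate: float
    linear_predictor: pd.Series  # per sample, X beta + C beta_clinical

    @property
    def causal_assays(self) -> list[str]:
        return list(self.beta_true.index[self.beta_true != 0.0])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "beta_true": self.beta_true.to_dict(),
            "beta_clinical_true": self.beta_clinical_true,
            "baseline_rate": self.baseline_rate,
            "linear_predictor": self.linear_predictor.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _assay_id(j: int) -> str:
    return f"A{j + 1:04d}"


def _draw_protein_matrix(cfg: CohortConfig, rng: np.random.Generator) -> tuple[np.ndarray, pd.Series]:
    """Equicorrelated Gaussian blocks nested in panels.

    Within a block of size m, cor(X_a, X_b) = block_rho via a shared factor:
    X = sqrt(rho) Z_block + sqrt(1 - rho) eps, so each column is standard
    normal marginally.
    """
    n, p = cfg.n_samples, cfg.n_assays
    per_panel = p // cfg.n_panels
    X = np.empty((n, p))
    panel = {}
    sq_rho, sq_res = np.sqrt(cfg.block_rho), np.sqrt(1.0 - cfg.block_rho)
    j = 0
    for ip in range(cfg.n_panels):
        for _ in range(per_panel // cfg.block_size):
            z = rng.standard_normal(n)
            eps = rng.standard_normal((n, cfg.block_size))
            X[:, j : j + cfg.block_size] = sq_rho * z[:, None] + sq_res * eps
            j += cfg.block_size
        for jj in range(ip * per_panel, (ip + 1) * per_panel):
            panel[_assay_id(jj)] = f"panel_{ip + 1}"
    return X, pd.Series(panel, name="panel")


def _draw_clinical(cfg: CohortConfig, rng: np.random.Generator, index: pd.Index) -> pd.DataFrame:
    n = cfg.n_samples
    table = pd.DataFrame(
        {
            "age": rng.uniform(40.0, 70.0, n).round(1),
            "sex": rng.integers(0, 2, n),
            "bmi": np.clip(rng.normal(27.3, 4.7, n), 16.0, 55.0).round(1),
            "ethnicity": rng.choice(ETHNICITIES, n, p=(0.90, 0.04, 0.03, 0.02, 0.01)),
            "smoking": rng.choice(SMOKING, n, p=(0.56, 0.34, 0.10)),
            "alcohol": rng.choice(ALCOHOL, n, p=(0.08, 0.52, 0.40)),
        },
        index=index,
    )
    return table  # family_history added after the linear predictor is known


def _clinical_linear_predictor(table: pd.DataFrame, beta: dict[str, float]) -> np.ndarray:
    lp = np.zeros(len(table))
    if "age" in beta:
        lp += beta["age"] * (table["age"].to_numpy() - 55.0) / 8.66  # uniform(40,70) s.d.
    if "sex" in beta:
        lp += beta["sex"] * (table["sex"].to_numpy() - 0.5)
    if "bmi" in beta:
        lp += beta["bmi"] * (table["bmi"].to_numpy() - 27.3) / 4.7
    if "smoking" in beta:
        lp += beta["smoking"] * (table["smoking"] == "current").to_numpy(dtype=float)
    return lp


def _expected_cases(rate: float, lp: np.ndarray, tau: float, shape: float) -> float:
    return float(np.sum(-np.expm1(-rate * np.exp(lp) * tau**shape)))


def _calibrate_rate(target: float, lp: np.ndarray, tau: float, shape: float) -> float:
    """Bisection on the baseline rate so expected incident cases ~ target
    (relative tolerance 1%)."""
    lo, hi = 1e-12, 1e4
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        e = _expected_cases(mid, lp, tau, shape)
        if abs(e - target) <= 0.01 * target:
            return mid
        if e < target:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def generate_cohort(
    config: CohortConfig,
) -> tuple[ProteinMatrix, ClinicalCovariates, OutcomeTable, SimulationTruth]:
    """Draw a full synthetic cohort; bit-reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sample_ids = pd.Index([f"S{i + 1:06d}" for i in range(config.n_samples)], name="sample_id")

    X, panel_of = _draw_protein_matrix(config, rng)
    clin_table = _draw_clinical(config, rng, sample_ids)

    lp = _clinical_linear_predictor(clin_table, config.beta_clinical)
    beta_true = np.zeros(config.n_assays)
    for j, b in zip(config.causal_assays, config.beta_protein):
        beta_true[j] = b
        lp += b * X[:, j]

    # family history: Bernoulli, optionally tilted by the true risk
    base_logit = np.log(0.12 / 0.88)
    fh_prob = 1.0 / (1.0 + np.exp(-(base_logit + config.family_history_assoc * lp)))
    clin_table["family_history"] = (rng.random(config.n_samples) < fh_prob).astype(int)

    tau, shape = config.admin_censor_years, config.weibull_shape
    rate = config.baseline_rate
    if config.target_case_count is not None:
        rate = _calibrate_rate(float(config.target_case_count), lp, tau, shape)

    # Weibull PH: cumulative hazard rate * t^shape * exp(lp); shape=1 is exponential
    e_std = rng.exponential(size=config.n_samples)
    t_event = (e_std / (rate * np.exp(lp))) ** (1.0 / shape)
    censor = np.full(config.n_samples, tau)
    if config.dropout_rate > 0:
        drop = rng.random(config.n_samples) < config.dropout_rate
        censor = np.where(drop, rng.uniform(0.0, tau, config.n_samples), censor)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)

    prevalent = np.zeros(config.n_samples, dtype=int)
    if config.prevalent_frac > 0:
        idx = rng.choice(config.n_samples, size=int(round(config.prevalent_frac * config.n_samples)), replace=False)
        prevalent[idx] = 1
        time[idx] = 0.0
        event[idx] = 0

    outcomes = OutcomeTable(
        pd.DataFrame({"time_years": time, "event": event, "prevalent": prevalent}, index=sample_ids),
        horizon_years=tau,
    )
    matrix = ProteinMatrix(
        values=pd.DataFrame(X, index=sample_ids, columns=[_assay_id(j) for j in range(config.n_assays)]),
        panel_of=panel_of,
        missing_mask=pd.DataFrame(
            False, index=sample_ids, columns=[_assay_id(j) for j in range(config.n_assays)]
        ),
    )
    if config.missing_rate > 0:
        matrix = inject_missingness(matrix, config.missing_rate, "MCAR", seed=int(rng.integers(2**31)))

    truth = SimulationTruth(
        beta_true=pd.Series(beta_true, index=matrix.assay_ids),
        beta_clinical_true=dict(config.beta_clinical),
        baseline_rate=rate,
        linear_predictor=pd.Series(lp, index=sample_ids),
    )
    return matrix, ClinicalCovariates(clin_table), outcomes, truth


def apply_incidence_filters(
    outcomes: OutcomeTable, min_incident_months: float = 6.0
) -> tuple[OutcomeTable, dict[str, int]]:
    """Drop prevalent cases and incident cases within the first
    ``min_incident_months`` of follow-up; other rows pass unchanged."""
    t = outcomes.table
    if (t["time_years"] < 0).any():
        raise ValueError("negative follow-up time")
    prevalent = t["prevalent"] == 1
    early = (t["event"] == 1) & (t["time_years"] < min_incident_months / 12.0)
    keep = ~(prevalent | early)
    counts = {
        "prevalent_removed": int(prevalent.sum()),
        "early_incident_removed": int((early & ~prevalent).sum()),
        "retained": int(keep.sum()),
    }
    return OutcomeTable(t.loc[keep].copy(), outcomes.horizon_years), counts


def inject_missingness(
    matrix: ProteinMatrix, rate: float, mechanism: str = "MCAR", seed: int = 0
) -> ProteinMatrix:
    """Mask a fraction ``rate`` of cells.

    ``MCAR`` masks cells uniformly; ``panel_block`` masks whole sample-panel
    blocks (failed-plate style) until the target fraction is reached.  The
    underlying values are preserved under the mask so imputation can be scored.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return matrix.copy()
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    mask = out.missing_mask.to_numpy()
    n, p = mask.shape
    if mechanism == "MCAR":
        mask |= rng.random((n, p)) < rate
    elif mechanism == "panel_block":
        panels = out.panel_of.loc[out.assay_ids].to_numpy()
        panel_names = list(dict.fromkeys(panels))
        pairs = [(i, pn) for pn in panel_names for i in range(n)]
        order = rng.permutation(len(pairs))
        target = int(np.ceil(rate * n * p))
        masked = int(mask.sum())
        for k in order:
            if masked >= target:
                break
            i, pn = pairs[k]
            cols = panels == pn
            newly = int((~mask[i, cols]).sum())
            mask[i, cols] = True
            masked += newly
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    out.missing_mask = pd.DataFrame(mask, index=out.sample_ids, columns=out.assay_ids)
    return out


def write_cohort(
    out_dir: str | Path,
    matrix: ProteinMatrix,
    covariates: ClinicalCovariates,
    outcomes: OutcomeTable,
    truth: SimulationTruth | None = None,
) -> None:
    """Standard on-disk layout: proteins TSV, covariates/outcomes CSV,
    panel map TSV, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_tsv(out / "proteins.tsv")
    matrix.panel_of.rename_axis("assay_id").to_csv(out / "panel_map.tsv", sep="\t")
    covariates.table.to_csv(out / "covariates.csv", index_label="sample_id")
    outcomes.to_csv(out / "outcomes.csv")
    if truth is not None:
        truth.to_json(out / "truth.json")
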