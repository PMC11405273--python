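"""Sample-level QC for NPX-like protein matrices.

A sample is flagged as an outlier when its standardized first or second
principal-component score, its median NPX, or its IQR of NPX lies more than
``sd_cutoff`` standard deviations from the cohort mean of that statistic.
PCA is computed jointly across assays on standardized, mean-imputed values
(the mean fill is used for the PCA only; the data are not modified).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .cohort import ProteinMatrix

__all__ = ["QCReport", "flag_sample_outliers"]

REASONS = ("pc_outlier", "median_npx_outlier", "iqr_outlier", "all_missing")


@dataclass
class QCReport:
    """Flagged samples with reasons, plus the threshold used."""

    flags: dict[str, list[str]] = field(default_factory=dict)
    sd_cutoff: float = 5.0

    @property
    def flagged_samples(self) -> list[str]:
        return sorted(self.flags)

    def _add(self, sample: str, reason: str) -> None:
        assert reason in REASONS
        self.flags.setdefault(sample, [])
        if reason not in self.flags[sample]:
            self.flags[sample].append(reason)

    def to_dict(self) -> dict:
        return {"sd_cutoff": self.sd_cutoff, "flags": self.flags}


def _zscores(x: np.ndarray) -> np.ndarray:
    sd = np.nanstd(x)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - np.nanmean(x)) / sd


def flag_sample_outliers(matrix: ProteinMatrix, sd_cutoff: float = 5.0) -> QCReport:
    """Flag outlying samples on PC1/PC2, median NPX and IQR of NPX."""
    obs = matrix.observed()
    if len(obs) < 3:
        raise ValueError("need at least 3 samples for outlier flagging")
    report = QCReport(sd_cutoff=sd_cutoff)

    values = obs.to_numpy(dtype=float)
    all_missing = np.isnan(values).all(axis=1)
    for sid in obs.index[all_missing]:
        warnings.warn(f"sample {sid} has no observed values; flagged", stacklevel=2)
        report._add(str(sid), "all_missing")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        med = np.nanmedian(values, axis=1)
        q75 = np.nanpercentile(values, 75, axis=1)
        q25 = np.nanpercentile(values, 25, axis=1)
    iqr = q75 - q25
    ok = ~all_missing
    for stat, reason in ((med, "median_npx_outlier"), (iqr, "iqr_outlier")):
        z = np.full(len(obs), 0.0)
        z[ok] = _zscores(stat[ok])
        for sid in obs.index[np.abs(z) > sd_cutoff]:
            report._add(str(sid), reason)

    # PCA on standardized assays, mean-filled (=> 0 after standardization)
    col_mean = np.nanmean(values[ok], axis=0)
    col_sd = np.nanstd(values[ok], axis=0)
    keep_cols = np.isfinite(col_sd) & (col_sd > 0)
    if keep_cols.sum() >= 2 and ok.sum() >= 3:
        Z = (values[np.ix_(ok, keep_cols)] - col_mean[keep_cols]) / col_sd[keep_cols]
        Z = np.nan_to_num(Z, nan=0.0)
        pcs = PCA(n_components=min(2, min(Z.shape)), svd_solver="full").fit_transform(Z)
        flagged = np.zeros(ok.sum(), dtype=bool)
        for k in range(pcs.shape[1]):
            flagged |= np.abs(_zscores(pcs[:, k])) > sd_cutoff
        for sid in obs.index[ok][flagged]:
            report._add(str(sid), "pc_outlier")
    return report
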