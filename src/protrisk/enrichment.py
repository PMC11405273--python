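"""Annotation enrichment and cross-disease predictor-sharing summaries.

Selected signatures are tested for over-representation of annotation labels
(tissue-specificity classes, pathway ids, panel ids — any user-supplied
assay -> labels map) with a two-sided Fisher exact test per label against a
background assay set, and Benjamini–Hochberg adjusted.  The sharing summary
tallies, per assay, how many disease signatures select it, across how many
clinical specialties, and its mean within-disease normalized weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationTable",
    "fisher_enrichment",
    "bh_adjust",
    "predictor_sharing_summary",
]


@dataclass
class AnnotationTable:
    """assay_id -> set of labels; assays without labels are allowed."""

    labels_of: dict[str, frozenset[str]]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationTable":
        """Two-column TSV (assay_id, label), one label per row."""
        df = pd.read_csv(path, sep="\t", header=0)
        mapping: dict[str, set[str]] = {}
        for assay, label in zip(df.iloc[:, 0], df.iloc[:, 1]):
            mapping.setdefault(str(assay), set()).add(str(label))
        return cls({k: frozenset(v) for k, v in mapping.items()})

    def vocabulary(self) -> list[str]:
        return sorted(set().union(*self.labels_of.values())) if self.labels_of else []

    def has_label(self, assay: str, label: str) -> bool:
        return label in self.labels_of.get(assay, frozenset())


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    selected: set[str] | list[str],
    background: set[str] | list[str],
    annotations: AnnotationTable,
) -> pd.DataFrame:
    """Two-sided Fisher exact test per label.

    2x2 counts per label: a = selected & labelled, b = selected & unlabelled,
    c = unselected & labelled, d = unselected & unlabelled; the odds ratio is
    the sample OR ad/bc with a Haldane 0.5 correction when any cell is zero.
    Returns one row per vocabulary label with a, b, c, d, odds_ratio,
    p_value, q_value.
    """
    sel = set(map(str, selected))
    bg = set(map(str, background))
    if not sel:
        raise ValueError("selected set is empty")
    if not sel <= bg:
        raise ValueError("selected must be a subset of background")
    rows = []
    for label in annotations.vocabulary():
        labelled = {a for a in bg if annotations.has_label(a, label)}
        a = len(sel & labelled)
        b = len(sel) - a
        c = len(labelled) - a
        d = len(bg) - len(sel) - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append({"label": label, "a": a, "b": b, "c": c, "d": d, "odds_ratio": orr, "p_value": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def predictor_sharing_summary(
    signatures: dict[str, dict[str, float]],
    specialty_of: dict[str, str],
    specific_weight_floor: float = 0.6,
) -> pd.DataFrame:
    """Per-assay sharing statistics across disease signatures.

    ``signatures`` maps disease -> {assay: model weight}; weights are
    normalized within each disease to that disease's top |weight|.  An assay
    is flagged ``disease_specific`` when it is selected for exactly one
    disease with normalized weight above the floor.
    """
    if len(signatures) < 2:
        raise ValueError("need at least two disease signatures")
    for disease in signatures:
        if disease not in specialty_of:
            raise ValueError(f"disease {disease!r} has no specialty label")
    per_assay: dict[str, list[tuple[str, float]]] = {}
    for disease, weights in signatures.items():
        if not weights:
            continue
        top = max(abs(w) for w in weights.values())
        if top == 0:
            continue
        for assay, w in weights.items():
            per_assay.setdefault(str(assay), []).append((disease, abs(w) / top))
    rows = []
    for assay, entries in sorted(per_assay.items()):
        diseases = [d for d, _ in entries]
        norm = np.array([v for _, v in entries])
        n_dis = len(set(diseases))
        rows.append(
            {
                "assay_id": assay,
                "n_diseases": n_dis,
                "n_specialties": len({specialty_of[d] for d in diseases}),
                "mean_normalized_weight": float(norm.mean()),
                "disease_specific": bool(n_dis == 1 and norm.max() > specific_weight_floor),
            }
        )
    return pd.DataFrame(rows).set_index("assay_id")
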