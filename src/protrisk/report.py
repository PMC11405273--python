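"""End-to-end report assembly: one JSON/Markdown summary per analysis run,
collecting the fitted suite, bootstrap comparisons, screening curves and
reclassification metrics."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import DeltaCResult, ReclassResult, ScreeningCurve
from .risk import ModelSuite

__all__ = ["assemble_report", "write_report"]


def _jsonable(obj):
    if isinstance(obj, DeltaCResult):
        return {
            "delta_mean": obj.delta_mean,
            "ci_low": obj.ci_low,
            "ci_high": obj.ci_high,
            "significant": obj.significant,
        }
    if isinstance(obj, ReclassResult):
        return {
            "cnri": obj.cnri,
            "margin": obj.margin,
            "idi": obj.idi,
            "horizon_years": obj.horizon_years,
        }
    if isinstance(obj, ScreeningCurve):
        return obj.table.to_dict(orient="records")
    if isinstance(obj, pd.DataFrame):
        return obj.reset_index().to_dict(orient="records")
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def assemble_report(
    suite: ModelSuite,
    comparisons: dict[str, DeltaCResult] | None = None,
    screening: dict[str, ScreeningCurve] | None = None,
    reclassification: ReclassResult | None = None,
    sharing: pd.DataFrame | None = None,
    extra: dict | None = None,
) -> dict:
    """Collect results into one JSON-serializable dictionary."""
    report = {
        "horizon_years": suite.horizon_years,
        "split_rule": suite.split_rule,
        "validation_c": dict(suite.validation_c),
        "best_protein_model": suite.best_protein_model,
        "model_sizes": {
            name: int((m.beta != 0).sum()) for name, m in suite.members.items()
        },
    }
    if comparisons:
        report["delta_c"] = _jsonable(comparisons)
    if screening:
        report["screening"] = _jsonable(screening)
    if reclassification is not None:
        report["reclassification"] = _jsonable(reclassification)
    if sharing is not None:
        report["predictor_sharing"] = _jsonable(sharing)
    if extra:
        report.update(_jsonable(extra))
    return report


def write_report(report: dict, out_dir: str | Path, stem: str = "report") -> None:
    """Write the report as JSON plus a short Markdown summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{stem}.json").write_text(json.dumps(_jsonable(report), indent=1))

    lines = ["# Risk-signature evaluation report", ""]
    lines.append(f"Analysis horizon: {report['horizon_years']} years; split rule: {report['split_rule']}")
    lines.append("")
    lines.append("| model | validation C | nonzero features |")
    lines.append("|---|---|---|")
    for name, c in report["validation_c"].items():
        lines.append(f"| {name} | {c:.3f} | {report['model_sizes'][name]} |")
    if report.get("best_protein_model"):
        lines.append("")
        lines.append(f"Best protein signature: **{report['best_protein_model']}**")
    if "delta_c" in report:
        lines.append("")
        lines.append("## Bootstrap C-index comparisons")
        for name, d in report["delta_c"].items():
            tag = "significant" if d["significant"] else "not significant"
            lines.append(
                f"- {name}: delta C = {d['delta_mean']:.3f} "
                f"(95% CI {d['ci_low']:.3f} to {d['ci_high']:.3f}; {tag})"
            )
    if "reclassification" in report:
        r = report["reclassification"]
        lines.append("")
        lines.append(
            f"Reclassification: cNRI = {r['cnri']:.3f} (margin {r['margin']}), IDI = {r['idi']:.4f}"
        )
    (out / f"{stem}.md").write_text("\n".join(lines) + "\n")
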