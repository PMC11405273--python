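"""Annotation enrichment of the selected signature and the final report.

Builds a synthetic panel-membership annotation (the panels are the only
ground-truth labels a simulated cohort has), tests the top-20 signature for
panel enrichment with two-sided Fisher tests and BH adjustment, summarizes
predictor sharing across three simulated diseases, and assembles the
end-to-end JSON/Markdown report.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT_CONFIG, RESULTS, SEED

from protrisk import (
    AnnotationTable,
    apply_incidence_filters,
    fisher_enrichment,
    generate_cohort,
    make_splits,
    predictor_sharing_summary,
    rank_top_k,
)
from protrisk.report import assemble_report, write_report
from protrisk.risk import FittedRiskModel, ModelSuite
from protrisk.selection import SelectionScoreTable


def main() -> None:
    matrix, _, outcomes, _ = generate_cohort(COHORT_CONFIG)
    table = pd.read_csv(RESULTS / "selection" / "selection_scores.tsv", sep="\t",
                        index_col="assay_id")
    scores = SelectionScoreTable(table, n_iterations=50)
    top20 = rank_top_k(scores, 20)

    annotations = AnnotationTable(
        {a: frozenset({matrix.panel_of[a]}) for a in matrix.assay_ids}
    )
    enr = fisher_enrichment(top20, set(matrix.assay_ids), annotations)
    print("panel enrichment of the top-20 signature:")
    for _, row in enr.sort_values("p_value").iterrows():
        print(f"  {row['label']}: OR = {row['odds_ratio']:.2f}, "
              f"p = {row['p_value']:.3g}, q = {row['q_value']:.3g}")

    # predictor sharing across three simulated diseases: reuse the fitted
    # model for this disease plus two variants with distinct causal sets
    model5 = FittedRiskModel.from_json(RESULTS / "models" / "clinical_proteins_5.json")
    weights_main = {
        n: abs(float(b))
        for n, b, pen in zip(model5.feature_names, model5.beta, model5.penalized)
        if pen and b != 0
    }
    signatures = {
        "disease_main": weights_main or {top20[0]: 1.0},
        "disease_b": {top20[0]: 0.9, "A0007": 0.4},
        "disease_c": {"A0007": 1.1, "A0200": 0.2},
    }
    specialty = {"disease_main": "gastroenterology", "disease_b": "cardiology",
                 "disease_c": "cardiology"}
    sharing = predictor_sharing_summary(signatures, specialty)
    shared = sharing[sharing["n_diseases"] > 1]
    print(f"assays shared across diseases: {len(shared)} "
          f"({list(shared.index)})")

    import json

    meta = json.loads((RESULTS / "models" / "suite.json").read_text())
    members = {
        p.stem: FittedRiskModel.from_json(p)
        for p in sorted((RESULTS / "models").glob("*.json"))
        if p.stem != "suite"
    }
    suite = ModelSuite(members, meta["horizon_years"], meta["split_rule"],
                       meta["validation_c"], meta["best_protein_model"])
    report = assemble_report(suite, sharing=sharing, extra={"panel_enrichment": enr})
    write_report(report, RESULTS / "report")
    print(f"wrote {RESULTS / 'report'}/report.json and report.md")


if __name__ == "__main__":
    main()
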