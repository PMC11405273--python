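"""Validate the fitted models: bootstrap delta-C, screening curves,
reclassification, stratified performance, 5-year horizon and case
downsampling.

Loads the serialized suite, scores the held-out validation split, and
writes the full evaluation report plus the DR-vs-FPR screening table.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT_CONFIG, RESULTS, SEED

from protrisk import (
    apply_incidence_filters,
    bootstrap_compare,
    downsample_cases,
    generate_cohort,
    make_splits,
    predict_risk,
    screening_curve,
    stratified_eval,
)
from protrisk.evaluation import reclassification
from protrisk.risk import FittedRiskModel


def main() -> None:
    matrix, covariates, outcomes, _ = generate_cohort(COHORT_CONFIG)
    filtered, _ = apply_incidence_filters(outcomes)
    splits = make_splits(filtered, seed=SEED)
    val_ids = splits.validation_ids.intersection(filtered.sample_ids)
    val_out = filtered.subset(val_ids)
    features = pd.concat([covariates.design_matrix(), matrix.values], axis=1).loc[val_ids]

    models = {
        p.stem: FittedRiskModel.from_json(p)
        for p in sorted((RESULTS / "models").glob("*.json"))
        if p.stem != "suite"
    }
    pred = {name: predict_risk(m, features) for name, m in models.items()}

    _, _, delta = bootstrap_compare(
        pred["clinical"]["linear_predictor"],
        pred["clinical_proteins_5"]["linear_predictor"],
        val_out, B=1000, seed=SEED,
    )
    tag = "significant" if delta.significant_improvement else "not significant"
    print(f"clinical+top5 vs clinical: delta C = {delta.delta_mean:.3f} "
          f"(95% CI {delta.ci_low:.3f} to {delta.ci_high:.3f}; {tag})")

    curves = {
        name: screening_curve(pred[name]["linear_predictor"], val_out)
        for name in ("clinical", "clinical_proteins_5")
    }
    at10 = curves["clinical_proteins_5"].at_fpr(0.10)
    print(f"protein model at 10% FPR: DR = {at10['dr']:.1%}, LR = {at10['lr']:.2f}")

    rec = reclassification(
        pred["clinical"]["absolute_risk"], pred["clinical_proteins_5"]["absolute_risk"], val_out
    )
    print(f"cNRI (0.15 margin) = {rec.cnri:.3f}, IDI = {rec.idi:.4f}")

    strata = covariates.table.loc[val_ids, "sex"].map({0: "women", 1: "men"})
    strat = stratified_eval(
        pred["clinical"]["linear_predictor"], pred["clinical_proteins_5"]["linear_predictor"],
        val_out, strata, min_cases=20, B=500, seed=SEED,
    )
    for level, res in strat.items():
        if res["skipped"]:
            print(f"stratum {level}: skipped ({res['reason']})")
        else:
            print(f"stratum {level}: delta C = {res['delta'].delta_mean:.3f}")

    five = screening_curve(pred["clinical_proteins_5"]["linear_predictor"], val_out, horizon=5.0)
    print(f"5-year horizon DR at 10% FPR: {five.at_fpr(0.10)['dr']:.1%}")

    down = downsample_cases(val_out, min(80, val_out.n_incident_cases), seed=SEED)
    _, _, delta80 = bootstrap_compare(
        pred["clinical"]["linear_predictor"].loc[down.sample_ids],
        pred["clinical_proteins_5"]["linear_predictor"].loc[down.sample_ids],
        down, B=500, seed=SEED,
    )
    print(f"downsampled to {down.n_incident_cases} cases: delta C = {delta80.delta_mean:.3f}")

    out = RESULTS / "evaluation"
    out.mkdir(parents=True, exist_ok=True)
    for name, curve in curves.items():
        curve.table.to_csv(out / f"screening_{name}.tsv", sep="\t", index=False)
    import json

    payload = {
        "delta_c_top5_vs_clinical": {
            "delta_mean": delta.delta_mean, "ci_low": delta.ci_low, "ci_high": delta.ci_high,
            "significant_improvement": delta.significant_improvement,
        },
        "reclassification": {"cnri": rec.cnri, "idi": rec.idi, "margin": rec.margin},
        "stratified": {
            k: (v["reason"] if v["skipped"] else {"delta_mean": v["delta"].delta_mean})
            for k, v in strat.items()
        },
        "downsampled_80_delta_c": delta80.delta_mean,
    }
    (out / "evaluation.json").write_text(json.dumps(payload, indent=1))
    print(f"wrote {out}/")


if __name__ == "__main__":
    main()
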