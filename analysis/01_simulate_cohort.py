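"""Simulate the reference proteomic cohort and apply the inclusion filters.

Writes the full per-sample tables (protein TSV with empty cell = missing,
covariates, outcomes, truth) under scratch/cohort/ — they are bulky and
regenerable from the seed — and the compact cohort summary under
results/cohort/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT_CONFIG, RESULTS, SCRATCH

from protrisk import apply_incidence_filters, generate_cohort
from protrisk.cohort import write_cohort


def main() -> None:
    matrix, covariates, outcomes, truth = generate_cohort(COHORT_CONFIG)
    filtered, counts = apply_incidence_filters(outcomes)

    write_cohort(SCRATCH / "cohort", matrix, covariates, outcomes, truth)
    filtered.to_csv(SCRATCH / "cohort" / "outcomes_filtered.csv")

    out = RESULTS / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    summary = {
        **counts,
        "n_samples": len(matrix.sample_ids),
        "n_assays": len(matrix.assay_ids),
        "incident_cases": filtered.n_incident_cases,
        "horizon_years": filtered.horizon_years,
        "causal_assays": truth.causal_assays,
        "causal_betas": [float(truth.beta_true[a]) for a in truth.causal_assays],
        "calibrated_baseline_rate": truth.baseline_rate,
    }
    (out / "cohort_summary.json").write_text(json.dumps(summary, indent=1))

    print(f"cohort: {len(matrix.sample_ids)} samples x {len(matrix.assay_ids)} assays "
          f"({matrix.missing_mask.to_numpy().mean():.1%} cells missing)")
    print(f"exclusions: {counts['prevalent_removed']} prevalent, "
          f"{counts['early_incident_removed']} incident <6 months")
    print(f"retained: {counts['retained']} samples, "
          f"{filtered.n_incident_cases} incident cases within "
          f"{filtered.horizon_years:.0f} years")
    print(f"causal assays: {truth.causal_assays}")
    print(f"wrote {SCRATCH / 'cohort'}/ (full tables) and {out}/cohort_summary.json")


if __name__ == "__main__":
    main()
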