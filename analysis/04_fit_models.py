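"""Fit the benchmark and protein-augmented regularized Cox models.

Reads the selection scores from results/selection/, fits the model suite
(clinical benchmark; clinical + top-20/10/5 proteins; proteins-only top-5)
on the training split with clinical covariates unpenalized in the augmented
members, and serializes the frozen models for downstream evaluation and
external transfer.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT_CONFIG, RESULTS, SEED

from protrisk import apply_incidence_filters, fit_model_suite, generate_cohort, make_splits
from protrisk.selection import SelectionScoreTable


def main() -> None:
    matrix, covariates, outcomes, _ = generate_cohort(COHORT_CONFIG)
    filtered, _ = apply_incidence_filters(outcomes)
    splits = make_splits(filtered, seed=SEED)

    table = pd.read_csv(RESULTS / "selection" / "selection_scores.tsv", sep="\t",
                        index_col="assay_id")
    scores = SelectionScoreTable(table, n_iterations=50)

    suite = fit_model_suite(matrix, covariates, filtered, splits, scores,
                            cv_folds=5, seed=SEED)
    out = RESULTS / "models"
    suite.save(out)
    for name, c in suite.validation_c.items():
        nonzero = int((suite[name].beta != 0).sum())
        print(f"{name:22s} validation C = {c:.3f} ({nonzero} nonzero features)")
    print(f"best protein signature: {suite.best_protein_model}")
    print(f"wrote {out}/")


if __name__ == "__main__":
    main()
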