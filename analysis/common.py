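"""Shared study conditions for the numbered analysis drivers.

One reference synthetic disease: 4,000 participants, 600 assays in
equicorrelated blocks of 10 (rho = 0.3) across 4 panels, five causal
proteins with |log HR| from 0.5 to 1.5 per s.d., clinical effects on
age/sex/BMI/smoking, ~400 incident cases over a 10-year horizon and 2%
prevalent disease.  The imputation driver uses its own smaller cohort with
injected missingness (IMPUTE_CONFIG) so the forest step stays desk-scale.
"""

from pathlib import Path

from protrisk import CohortConfig
from protrisk.studies import RECOVERY_BETAS, RECOVERY_CAUSAL_AT

RESULTS = Path(__file__).resolve().parent.parent / "results"
# bulky regenerable artifacts (full matrices, per-sample tables) go here
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SEED = 2024

COHORT_CONFIG = CohortConfig(
    n_samples=4000,
    n_assays=600,
    n_panels=4,
    block_size=10,
    block_rho=0.3,
    causal_assays=RECOVERY_CAUSAL_AT,
    beta_protein=RECOVERY_BETAS,
    target_case_count=400,
    prevalent_frac=0.02,
    seed=SEED,
)

IMPUTE_CONFIG = CohortConfig(
    n_samples=1000,
    n_assays=48,
    n_panels=2,
    block_size=8,
    block_rho=0.5,
    baseline_rate=0.01,
    missing_rate=0.03,
    seed=SEED + 1,
)
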