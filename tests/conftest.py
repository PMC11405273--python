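import numpy as np
import pandas as pd
import pytest

from protrisk import CohortConfig, OutcomeTable, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with two causal proteins, shared across read-only tests."""
    cfg = CohortConfig(
        n_samples=800,
        n_assays=60,
        n_panels=2,
        block_size=10,
        block_rho=0.3,
        causal_assays=(2, 35),
        beta_protein=(1.0, -1.2),
        target_case_count=120,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def toy_outcomes():
    """Hand-sized outcome table: known prevalent/early/late composition."""
    table = pd.DataFrame(
        {
            "time_years": [0.0, 0.3, 2.0, 10.0],
            "event": [0, 1, 1, 0],
            "prevalent": [1, 0, 0, 0],
        },
        index=pd.Index(["P", "E", "L", "C"], name="sample_id"),
    )
    return OutcomeTable(table, horizon_years=10.0)


def brute_force_harrell(times, events, scores):
    """O(n^2) reference concordance: pair comparable iff the earlier time is
    an event; tied scores count 1/2; tied times are never comparable."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    scores = np.asarray(scores, float)
    conc = comp = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                comp += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    conc += 0.5
    return conc / comp
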