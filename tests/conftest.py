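import numpy as np
import pandas as pd
import pytest

from atacmotif.simulate import (
    default_activities,
    generate_acs_set,
    sample_motif_collection,
    simulate_counts,
)


@pytest.fixture(scope="session")
def small_study():
    """A compact planted study shared by scan/activity/integration tests.

    400 ACS x 15 motifs (5 active), moderate noise; small enough that any
    test using it stays fast while the planted structure is recoverable.
    """
    pwms = sample_motif_collection(15, seed=210)
    beta = default_activities(15, 5, (0.4, 1.0), seed=211)
    sequences, regions, truth = generate_acs_set(
        400, pwms=pwms, planting_prob=0.15, activities=beta,
        noise_sd=0.4, seed=212)
    counts = simulate_counts(truth, n_per_group=3, seed=213,
                             dispersion=0.2, mean_count=100)
    return {"pwms": pwms, "beta": beta, "sequences": sequences,
            "regions": regions, "truth": truth, "counts": counts}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
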