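import numpy as np
import pandas as pd
import pytest

from physiage import (
    CohortSimParams,
    MitoHealthSimParams,
    PUBLISHED_MODEL,
    default_config,
    reference_normalization,
    score_table,
    simulate_mitohealth_cohort,
    simulate_nhanes_cohort,
)


@pytest.fixture(scope="session")
def phenoage_config():
    return default_config()


@pytest.fixture(scope="session")
def default_cohort():
    """Default NHANES-like cohort, fixed seed, shared across tests."""
    return simulate_nhanes_cohort(CohortSimParams(seed=1))


@pytest.fixture(scope="session")
def reference_nf():
    """NF table for the published clock, from the default synthetic cohort."""
    return reference_normalization(seed=0)


@pytest.fixture(scope="session")
def scored_mitohealth(reference_nf):
    """4-group cohort scored with the published clock."""
    cohort = simulate_mitohealth_cohort(MitoHealthSimParams(seed=5))
    return score_table(PUBLISHED_MODEL, reference_nf, cohort)


@pytest.fixture()
def toy_scored_test():
    """Small scored table with known alive/deceased deltaAge values."""
    rng = np.random.default_rng(42)
    n_alive, n_dead = 40, 12
    return pd.DataFrame(
        {
            "id": range(n_alive + n_dead),
            "vital_status": ["alive"] * n_alive + ["deceased"] * n_dead,
            "delta_age": np.concatenate(
                [rng.normal(0.5, 4.0, n_alive), rng.normal(6.0, 4.0, n_dead)]
            ),
        }
    )
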