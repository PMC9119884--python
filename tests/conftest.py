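import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from betadelta.synthetic import (
    CohortConfig, recovery_config, simulate_cohort_dataset,
)


@pytest.fixture(scope="session")
def small_recovery():
    """A small fine-grid cohort with its simulated dataset (noise-free)."""
    cfg = recovery_config(seed=11, n_per_group=8)
    cohort, dataset = simulate_cohort_dataset(cfg)
    return cfg, cohort, dataset


@pytest.fixture(scope="session")
def study_dataset():
    """Study-condition bundle: 26/23/25 subjects on the 5-row 12-20 grid."""
    from betadelta.synthetic import default_config

    cfg = default_config(seed=3)
    cohort, dataset = simulate_cohort_dataset(cfg)
    return cfg, cohort, dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
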