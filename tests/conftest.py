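import numpy as np
import pytest

from teepi.config import Config
from teepi.synthetic_cohort import (
    CohortSpec,
    average_replicates,
    generate_cohort,
    simulate_signal,
)


@pytest.fixture(scope="session")
def small_config():
    # 5 windows per side keeps the synthetic chromosomes small and fast
    return Config(n_windows_per_side=5)


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_te=20, n_genes=30, n_windows_per_side=5, seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_tracks(small_cohort, small_config):
    return simulate_signal(small_cohort.truth, small_cohort, small_config.bin_bp)


@pytest.fixture(scope="session")
def small_averaged(small_tracks):
    return average_replicates(small_tracks)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
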