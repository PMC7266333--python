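import numpy as np
import pytest
from hypothesis import settings

from devtraj import simulate

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-child mixed cohort (typical / global delay / speech delay)."""
    cohort, truth = simulate.generate_cohort(
        [(simulate.TYPICAL, 6), (simulate.GLOBAL_DELAY, 4), (simulate.SPEECH_DELAY, 2)],
        seed=20,
    )
    return cohort, truth


@pytest.fixture(scope="session")
def separated_clusters():
    y, labels = simulate.generate_gaussian_clusters("separated", seed=7, n_per_cluster=20)
    return y, labels


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
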