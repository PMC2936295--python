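import numpy as np
import pytest

from dinet import simulate_timecourses, simulate_topology


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_grn():
    """A small ground-truth network shared by cheap integration tests."""
    return simulate_topology(n_tf=5, n_gene=30, n_edges=20, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_grn):
    return simulate_timecourses(small_grn, n_experiments=10, n_timepoints=4,
                                noise_sd=0.3, seed=12)
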