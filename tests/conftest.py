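import numpy as np
import pytest

from sgbold import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale paired test/retest dataset with the default study structure."""
    return simulate_dataset(SimConfig(n_subjects=6, n_nodes=8, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
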