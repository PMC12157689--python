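import numpy as np
import pytest

from poeqtl.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across tests."""
    cfg = SimConfig(n_trios=80, n_sites=400, n_genes=40, seed=123)
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
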