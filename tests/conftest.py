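import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scstalt import SimulationConfig, log_normalize, simulate_counts

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


#: small but non-trivial simulation shared across module tests
SMALL_CONFIG = SimulationConfig(n_genes=400, n_cells=600, snr=0.25, nonlinear_prop=0.2, seed=7)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_counts(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_lognorm(small_sim):
    return log_normalize(small_sim.counts)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
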