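import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from mgasnet.config import SimulationConfig
from mgasnet.synthdata import simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast toy study: 400 samples, 20 genes x 3 SNPs, 4 traits."""
    return SimulationConfig(
        n_samples=400,
        n_genes=20,
        snps_per_gene=(3, 3),
        n_traits=4,
        causal_genes=("G005",),
        n_ppi_nodes=60,
        planted_module_size=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
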