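import numpy as np
import pytest

from neuromass import (
    NodeParams,
    PlasticityParams,
    SimulationProtocol,
    simulate,
    synthetic_connectome,
)


@pytest.fixture(scope="session")
def alpha_node() -> NodeParams:
    """Pure alpha-subpopulation region (classical single-mass limit)."""
    return NodeParams(r_alpha=1.0)


@pytest.fixture(scope="session")
def small_connectome():
    return synthetic_connectome(n_nodes=10, seed=42, density=0.4, modules=2)


@pytest.fixture(scope="session")
def alpha_run(alpha_node):
    """Noise-free alpha-only run at default input (cached for reuse)."""
    proto = SimulationProtocol(
        t_total=90.0, t_discard=30.0, noise_enabled=False, seed=0
    )
    return simulate(None, alpha_node, PlasticityParams(enabled=False), proto)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
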