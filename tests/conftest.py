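import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mito_params():
    from metaspike.mito import MitoParams

    return MitoParams()


@pytest.fixture(scope="session")
def small_net_config():
    """A fast 200-neuron network for wiring/determinism tests."""
    from metaspike.network import NetworkConfig

    return NetworkConfig.scaled_down(seed=3, n_exc=160, n_inh=40)


@pytest.fixture(scope="session")
def scaled_config():
    from metaspike.network import NetworkConfig

    return NetworkConfig.scaled_down(seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
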