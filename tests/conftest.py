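import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_net():
    from cpinet import toy_network

    return toy_network()


@pytest.fixture
def toy_weighted_net():
    from cpinet import toy_weighted_network

    return toy_weighted_network()


@pytest.fixture
def block_network():
    """Structured generator output at its default study conditions."""
    from cpinet import GeneratorConfig, random_bipartite

    return random_bipartite(GeneratorConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
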