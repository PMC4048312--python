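import numpy as np
import pytest

from gtenet import GroundTruthNetwork, generate_er_network


@pytest.fixture(scope="session")
def small_net():
    """A 40-neuron sparse network used by fast dynamics tests."""
    return generate_er_network(40, 0.12, frac_excitatory=0.8, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def two_neuron_net():
    """Two unconnected neurons (minimal valid network)."""
    return GroundTruthNetwork(
        adjacency=np.zeros((2, 2), dtype=int),
        neuron_type=np.array([1, 1]),
        positions=np.array([[0.2, 0.2], [0.8, 0.8]]),
        frac_excitatory=1.0,
    )
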