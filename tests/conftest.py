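import numpy as np
import pytest

from punet import synth
from punet.graph import PPINetwork


@pytest.fixture(scope="session")
def default_instance():
    """The reference synthetic study (2,000 nodes, 60-node planted module)."""
    return synth.generate_instance(synth.SynthConfig())


@pytest.fixture(scope="session")
def small_instance():
    """A fast instance for protocol-level tests."""
    return synth.generate_instance(synth.SynthConfig(
        n_nodes=300, module_size=30, n_features=16, n_informative=8,
        effect_size=1.5, seed=7))


@pytest.fixture
def path_graph():
    """A - B - C path."""
    return PPINetwork.from_id_edges({("A", "B"): 900, ("B", "C"): 900})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
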