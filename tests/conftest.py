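import numpy as np
import pytest

from msnf.layout import make_layout
from msnf.simulate import make_template_set, sample_labels, uniform_chain


@pytest.fixture(scope="session")
def layout20():
    return make_layout(20)


@pytest.fixture(scope="session")
def templates20(layout20):
    return make_template_set(layout20, n_states=5, seed=1)


@pytest.fixture(scope="session")
def chain5():
    """Symmetric 5-state chain with a ~67 ms dwell at 250 Hz."""
    return uniform_chain(5, p_stay=0.94)


@pytest.fixture(scope="session")
def labels_long(chain5):
    """A long seeded label sequence for statistical oracles (n=1e5 at 250 Hz)."""
    return sample_labels(chain5, 100_000, 250.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
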