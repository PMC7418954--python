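import numpy as np
import pytest

from phylarynx import SimulationConfig, make_dataset, read_tree, simulate_tree


@pytest.fixture
def cherry():
    return read_tree("(A:1.0,B:1.0);")


@pytest.fixture
def three_tip():
    return read_tree("(A:1,(B:0.5,C:0.5):0.5);")


@pytest.fixture(scope="session")
def tree55():
    """A 55-tip, 79-My two-clade tree shared across slow tests."""
    from phylarynx import graft_trees

    tp = simulate_tree(26, seed=101, depth=65.0, prefix="P")
    tc = simulate_tree(29, seed=102, depth=55.0, prefix="C")
    return graft_trees(tp, tc, 79.0)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-config synthetic study, reused by read-only tests."""
    return make_dataset(SimulationConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(7)
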