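import numpy as np
import pytest
from hypothesis import settings

import failrecov as fr

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def lattice3() -> fr.Network:
    return fr.make_square_lattice(3, periodic=True)


@pytest.fixture(scope="session")
def lattice50() -> fr.Network:
    return fr.make_square_lattice(50, periodic=True)


@pytest.fixture(scope="session")
def single_node() -> fr.Network:
    return fr.Network(n=1, edges=np.zeros((0, 2), dtype=np.int64))


@pytest.fixture(scope="session")
def three_cycle() -> fr.Network:
    return fr.Network(n=3, edges=np.array([[0, 1], [0, 2], [1, 2]]))


def assert_simple_graph(net: fr.Network) -> None:
    """No self-loops, no duplicate edges, consistent degree sum."""
    assert np.all(net.edges[:, 0] != net.edges[:, 1])
    pairs = {tuple(e) for e in net.edges}
    assert len(pairs) == net.n_edges
    assert net.degrees().sum() == 2 * net.n_edges
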