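import numpy as np
import pytest

from mdlmotifs.census import enumerate_graphlets
from mdlmotifs.graphs import DirectedGraph


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def gamma3():
    return enumerate_graphlets(3, 3)


@pytest.fixture(scope="session")
def gamma34():
    return enumerate_graphlets(3, 4)


@pytest.fixture
def triangle_plus():
    """A 3-cycle {0,1,2} with a feeder edge 3->0 and an output edge 2->4."""
    return DirectedGraph(5, [(0, 1), (1, 2), (2, 0), (3, 0), (2, 4)])


def random_digraph(n: int, p: float, rng: np.random.Generator) -> DirectedGraph:
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    edges = [(int(i), int(j)) for i, j in zip(*np.nonzero(mask))]
    return DirectedGraph(n, edges)
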