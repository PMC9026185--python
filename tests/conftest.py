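import numpy as np
import pytest

from ihop import Graph, make_chain


@pytest.fixture
def chain6():
    return make_chain(6)


@pytest.fixture
def triangle():
    return Graph.from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_er_graph(n, p, rng):
    """Erdos-Renyi graph as an edge list (test-local helper)."""
    rows, cols = np.triu_indices(n, k=1)
    keep = rng.random(len(rows)) < p
    return Graph.from_edges(n, list(zip(rows[keep], cols[keep])))
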