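import networkx as nx
import pytest

from hlca.ppi_io import PPINetwork
from hlca.synthetic import SyntheticSpec, generate


@pytest.fixture
def triangle() -> PPINetwork:
    return PPINetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3() -> PPINetwork:
    return PPINetwork.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def two_cliques_bridge() -> PPINetwork:
    """Two disjoint 4-cliques joined by a single bridge edge."""
    edges = []
    left = ["a", "b", "c", "d"]
    right = ["e", "f", "g", "h"]
    for grp in (left, right):
        edges += [(grp[i], grp[j]) for i in range(4) for j in range(i + 1, 4)]
    edges.append(("d", "e"))
    return PPINetwork.from_edges(edges)


def random_ppi(n: int, p: float, seed: int) -> PPINetwork:
    """Connected-enough random network for oracle tests."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    edges = [(f"n{u}", f"n{v}") for u, v in g.edges]
    if not edges:
        edges = [("n0", "n1")]
    return PPINetwork.from_edges(edges)


@pytest.fixture(scope="session")
def ci_fixture():
    """The default synthetic benchmark: 120 nodes, 10 planted complexes."""
    return generate(SyntheticSpec())
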