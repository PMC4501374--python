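from itertools import combinations

import networkx as nx
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from kassembly import make_graph

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def triangle_with_pendant():
    """Triangle 0-1-2 plus vertex 3 adjacent to 0 and 1."""
    return make_graph(4, [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3)])


@pytest.fixture
def path3():
    return make_graph(3, [(0, 1), (1, 2)])


@pytest.fixture
def k4():
    return nx.complete_graph(4)


@pytest.fixture
def k5():
    return nx.complete_graph(5)


@pytest.fixture
def c4():
    return nx.cycle_graph(4)


@pytest.fixture
def c6():
    return nx.cycle_graph(6)


@pytest.fixture
def two_triangles():
    """Two vertex-disjoint triangles."""
    return make_graph(6, [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])


@st.composite
def small_graphs(draw, min_n=2, max_n=8):
    """Arbitrary simple graphs on up to ``max_n`` vertices."""
    n = draw(st.integers(min_value=min_n, max_value=max_n))
    pairs = list(combinations(range(n), 2))
    edges = draw(st.lists(st.sampled_from(pairs), unique=True, max_size=len(pairs)))
    return make_graph(n, edges)


@st.composite
def graph_subset_threshold(draw, max_n=8, max_k=4):
    """A graph, a vertex subset, and a threshold."""
    G = draw(small_graphs(max_n=max_n))
    nodes = sorted(G.nodes())
    S = draw(st.sets(st.sampled_from(nodes)))
    k = draw(st.integers(min_value=1, max_value=max_k))
    return G, S, k
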