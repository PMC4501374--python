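from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from kassembly import (
    bernoulli_graph,
    directed_kcore_filter,
    enumerate_minimal_kcores,
    is_kcore,
    is_minimal_kcore,
    make_graph,
    maximal_cliques,
    maximum_kcore,
)


class TestIsKcore:
    def test_complete_graph(self, k4):
        assert is_kcore(k4, set(k4.nodes()), 3)
        assert not is_kcore(k4, {0, 1, 2}, 3)

    def test_cycle_is_two_core(self, c6):
        assert is_kcore(c6, set(c6.nodes()), 2)

    def test_empty_set_is_not_a_kcore(self, k4):
        assert not is_kcore(k4, set(), 1)


class TestMaximumKcore:
    def test_pendant_peeled_off_cycle(self):
        G = nx.cycle_graph(5)
        G.add_edge(0, 5)
        result = maximum_kcore(G, 2)
        assert result.core == {0, 1, 2, 3, 4}
        assert result.removal_order == [(5, 1)]

    def test_too_high_threshold_empties(self, k4):
        assert maximum_kcore(k4, 4).core == set()

    def test_disconnected_core_allowed(self, two_triangles):
        assert maximum_kcore(two_triangles, 2).core == set(range(6))

    def test_core_and_removals_partition_vertices(self):
        G = bernoulli_graph(15, 0.3, rng=2)
        result = maximum_kcore(G, 2)
        removed = {v for v, _ in result.removal_order}
        assert result.core | removed == set(G.nodes())
        assert not result.core & removed

    @pytest.mark.parametrize("seed", range(5))
    def test_core_is_tie_break_invariant(self, seed):
        # any valid min-degree peeling order yields the same core set
        G = bernoulli_graph(12, 0.35, rng=seed)
        expected = maximum_kcore(G, 2).core
        rng = np.random.default_rng(seed)
        for _ in range(5):
            adj = {v: set(G[v]) for v in G.nodes()}
            while adj:
                low = min(len(nbrs) for nbrs in adj.values())
                if low >= 2:
                    break
                choices = [v for v, nbrs in adj.items() if len(nbrs) == low]
                v = choices[rng.integers(len(choices))]
                for u in adj[v]:
                    adj[u].discard(v)
                del adj[v]
            assert set(adj) == expected

    @pytest.mark.parametrize("seed", range(4))
    def test_core_contains_every_kcore(self, seed):
        # the peel survivor is the union of all k-cores
        G = bernoulli_graph(9, 0.4, rng=100 + seed)
        k = 2
        core = maximum_kcore(G, k).core
        nodes = sorted(G.nodes())
        for size in range(1, len(nodes) + 1):
            for S in combinations(nodes, size):
                if is_kcore(G, set(S), k):
                    assert set(S) <= core


class TestIsMinimalKcore:
    def test_triangle_inside_k4(self, k4):
        assert is_minimal_kcore(k4, {0, 1, 2}, 2)

    def test_k4_itself_not_minimal_at_2(self, k4):
        assert not is_minimal_kcore(k4, set(k4.nodes()), 2)

    def test_cycle_is_minimal(self, c6):
        assert is_minimal_kcore(c6, set(c6.nodes()), 2)

    def test_clique_on_k_plus_one_vertices(self):
        # every (k+1)-subset of a maximal clique induces a minimal k-core
        G = bernoulli_graph(9, 0.6, rng=8)
        for clique in maximal_cliques(G):
            for k in range(1, len(clique)):
                for sub in combinations(clique, k + 1):
                    assert is_minimal_kcore(G, set(sub), k)


class TestMaximalCliques:
    def test_k4_minus_edge(self):
        G = nx.complete_graph(4)
        G.remove_edge(0, 1)
        assert maximal_cliques(G) == [(0, 2, 3), (1, 2, 3)]

    def test_cycle_cliques_are_edges(self):
        C5 = nx.cycle_graph(5)
        assert maximal_cliques(C5) == sorted(
            tuple(sorted(e)) for e in C5.edges()
        )

    def test_matches_exhaustive_subset_scan(self):
        G = bernoulli_graph(10, 0.5, rng=1)
        nodes = sorted(G.nodes())
        brute = []
        for size in range(1, len(nodes) + 1):
            for S in combinations(nodes, size):
                if all(G.has_edge(u, v) for u, v in combinations(S, 2)):
                    if all(
                        any(not G.has_edge(w, v) for v in S)
                        for w in nodes
                        if w not in S
                    ):
                        brute.append(tuple(S))
        assert maximal_cliques(G) == sorted(brute)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_networkx(self, seed):
        G = bernoulli_graph(12, 0.5, rng=50 + seed)
        ref = sorted(tuple(sorted(c)) for c in nx.find_cliques(G))
        assert maximal_cliques(G) == ref


class TestMinimalCoreStructure:
    @pytest.mark.parametrize("seed,k", [(0, 2), (1, 2), (2, 3), (3, 3)])
    def test_cores_are_connected_and_large_enough(self, seed, k):
        G = bernoulli_graph(11, 0.5, rng=seed)
        core_set = maximum_kcore(G, k).core
        for core in enumerate_minimal_kcores(G, k).cores:
            assert len(core) >= k + 1
            assert nx.is_connected(G.subgraph(core))
            assert set(core) <= core_set


class TestDirectedFilter:
    def test_minimal_one_cores_are_edges_and_need_both_arcs(self):
        # undirected minimal 1-cores are single edges; under a cyclic
        # orientation one endpoint of every edge lacks its in (resp. out)
        # neighbor inside the pair, so nothing survives
        D = nx.DiGraph([(0, 1), (1, 2), (2, 0)])
        assert directed_kcore_filter(D, 1, "in") == []
        assert directed_kcore_filter(D, 1, "out") == []

    def test_bidirected_edges_survive_at_k1(self):
        D = nx.DiGraph([(0, 1), (1, 0), (1, 2), (2, 1)])
        assert directed_kcore_filter(D, 1, "in") == [(0, 1), (1, 2)]
        assert directed_kcore_filter(D, 1, "out") == [(0, 1), (1, 2)]

    def test_inward_star_fails_both_modes(self):
        # all edges point at the hub: each undirected minimal 1-core is one
        # edge, and one endpoint always lacks the required in/out degree
        D = nx.DiGraph([(1, 0), (2, 0), (3, 0)])
        assert directed_kcore_filter(D, 1, "out") == []
        assert directed_kcore_filter(D, 1, "in") == []

    def test_orientation_breaks_some_cores(self):
        # two disjoint triangles: one fully bidirected, one cyclically
        # oriented; only the bidirected one has in-degree 2 throughout
        arcs = [(0, 1), (1, 2), (2, 0)]
        D = nx.DiGraph(arcs + [(v, u) for u, v in arcs] + [(3, 4), (4, 5), (5, 3)])
        assert directed_kcore_filter(D, 2, "in") == [(0, 1, 2)]
        assert directed_kcore_filter(D, 2, "out") == [(0, 1, 2)]

    def test_mode_validated(self):
        with pytest.raises(Exception):
            directed_kcore_filter(nx.DiGraph(), 1, "sideways")
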