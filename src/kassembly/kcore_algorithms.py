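"""k-core predicates, greedy maximum-k-core peeling, minimality testing,
Bron–Kerbosch maximal cliques, and the directed-degree filter.

A k-core here is any nonempty induced subgraph of minimum degree >= k;
neither maximality nor connectedness is required (Seidman's maximal k-core
is recovered as the output of :func:`maximum_kcore`, which may be
disconnected).  The empty set is deliberately not a k-core, so "the graph
contains a k-core" always means a nonempty one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import networkx as nx

from ._bitcore import (
    is_minimal_kcore_mask,
    iter_bits,
    masks_from_graph,
)
from .graph_model import GraphValidationError

__all__ = [
    "PeelResult",
    "is_kcore",
    "maximum_kcore",
    "is_minimal_kcore",
    "maximal_cliques",
    "directed_kcore_filter",
]


def _check_threshold(k: int) -> None:
    if not isinstance(k, (int,)) or isinstance(k, bool) or k < 1:
        raise GraphValidationError(f"threshold k must be an integer >= 1, got {k!r}")


def _check_subset(G: nx.Graph, S: Iterable[int]) -> set[int]:
    S = set(S)
    missing = S - set(G.nodes())
    if missing:
        raise GraphValidationError(f"vertices {sorted(missing)} are not in the graph")
    return S


@dataclass
class PeelResult:
    """Outcome of the greedy minimum-degree peel.

    ``core`` is the (possibly empty, possibly disconnected) maximum k-core;
    ``removal_order`` records each deleted vertex with its degree at the
    moment of removal.
    """

    core: set[int]
    removal_order: list[tuple[int, int]] = field(default_factory=list)


def is_kcore(G: nx.Graph, S: Iterable[int], k: int) -> bool:
    """True iff ``S`` is nonempty and every member has >= k neighbors in ``S``."""
    _check_threshold(k)
    S = _check_subset(G, S)
    if not S:
        return False
    return all(sum(1 for u in G[v] if u in S) >= k for v in S)


def maximum_kcore(G: nx.Graph, k: int) -> PeelResult:
    """Greedy peel: delete a minimum-degree vertex while its degree is < k.

    The surviving vertex set is the unique maximum k-core — the union of all
    k-cores of ``G`` — and does not depend on tie-breaking; ties are broken
    on the smallest vertex id so that ``removal_order`` is reproducible.
    """
    _check_threshold(k)
    adj = {v: set(G[v]) for v in G.nodes()}
    order: list[tuple[int, int]] = []
    while adj:
        v = min(adj, key=lambda u: (len(adj[u]), u))
        deg = len(adj[v])
        if deg >= k:
            break
        order.append((v, deg))
        for u in adj[v]:
            adj[u].discard(v)
        del adj[v]
    return PeelResult(core=set(adj), removal_order=order)


def is_minimal_kcore(G: nx.Graph, S: Iterable[int], k: int) -> bool:
    """True iff ``S`` is a k-core and no proper subset of it induces a k-core.

    Equivalent test: for every v in S, the peel of ``G[S \\ {v}]`` is empty
    (any proper k-core subset would survive the peel after deleting some
    vertex it avoids).
    """
    _check_threshold(k)
    S = _check_subset(G, S)
    if not S:
        return False
    H = G.subgraph(S)
    nodes, adj = masks_from_graph(H)
    mask = (1 << len(nodes)) - 1
    return is_minimal_kcore_mask(adj, mask, k)


def maximal_cliques(G: nx.Graph) -> list[tuple[int, ...]]:
    """All maximal cliques, each once, via Bron–Kerbosch backtracking.

    The pivot is chosen from ``candidates ∪ not`` as the vertex with the
    fewest disconnections to the candidate set (ties on the smallest id),
    and only candidates not adjacent to the pivot are extended.
    """
    nodes, adj = masks_from_graph(G)
    n = len(nodes)
    out: list[tuple[int, ...]] = []
    if n == 0:
        return out

    def extend(compsub: int, candidates: int, not_set: int) -> None:
        if candidates == 0 and not_set == 0:
            out.append(tuple(nodes[i] for i in iter_bits(compsub)))
            return
        if candidates == 0:
            return
        pool = candidates | not_set
        pivot = min(
            iter_bits(pool),
            key=lambda v: ((candidates & ~adj[v]).bit_count(), v),
        )
        for v in iter_bits(candidates & ~adj[pivot]):
            bit = 1 << v
            extend(compsub | bit, candidates & adj[v], not_set & adj[v])
            candidates &= ~bit
            not_set |= bit

    extend(0, (1 << n) - 1, 0)
    return sorted(out)


def directed_kcore_filter(
    D: nx.DiGraph, k: int, mode: Literal["in", "out"]
) -> list[tuple[int, ...]]:
    """Directed extension: minimal k-cores of the underlying undirected graph
    that are still k-cores by in-degree (``mode='in'``) or out-degree
    (``mode='out'``) within the set.

    This filter can miss directed structures that are not minimal k-cores of
    the undirected projection; it mirrors the undirected-first procedure and
    inherits that incompleteness.
    """
    from .enumeration import enumerate_minimal_kcores

    _check_threshold(k)
    if mode not in ("in", "out"):
        raise GraphValidationError(f"mode must be 'in' or 'out', got {mode!r}")
    U = nx.Graph()
    U.add_nodes_from(D.nodes())
    U.add_edges_from((u, v) for u, v in D.edges() if u != v)
    result = enumerate_minimal_kcores(U, k)
    kept: list[tuple[int, ...]] = []
    for core in result.cores:
        inside = set(core)
        if mode == "in":
            ok = all(
                sum(1 for u in D.predecessors(v) if u in inside) >= k for v in core
            )
        else:
            ok = all(
                sum(1 for u in D.successors(v) if u in inside) >= k for v in core
            )
        if ok:
            kept.append(core)
    return kept
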