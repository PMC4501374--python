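"""Bitmask graph kernels shared by the peeling and enumeration code.

Vertex subsets of a graph with up to a few hundred vertices are represented
as Python integers (bit ``i`` set means vertex ``nodes[i]`` is in the set),
and adjacency as a list of neighbor masks.  Subset copy, intersection and
popcount are then single int operations, which is what makes the
backtracking enumerator usable at the simulation-study sizes.
"""

from __future__ import annotations

from typing import Iterator

import networkx as nx


def masks_from_graph(G: nx.Graph) -> tuple[list[int], list[int]]:
    """Return ``(nodes, adj)``: sorted node labels and per-node neighbor masks."""
    nodes = sorted(G.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * len(nodes)
    for u, v in G.edges():
        iu, iv = index[u], index[v]
        if iu == iv:
            continue
        adj[iu] |= 1 << iv
        adj[iv] |= 1 << iu
    return nodes, adj


def iter_bits(mask: int) -> Iterator[int]:
    """Yield the set bit positions of ``mask`` in increasing order."""
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def full_mask(n: int) -> int:
    return (1 << n) - 1


def peel_mask(adj: list[int], live: int, k: int) -> int:
    """Maximum k-core of the subgraph induced by ``live``, as a mask.

    Repeatedly removes every vertex whose degree inside ``live`` is below
    ``k``; the surviving set is order-independent.
    """
    while live:
        removed = 0
        m = live
        while m:
            low = m & -m
            v = low.bit_length() - 1
            if (adj[v] & live).bit_count() < k:
                removed |= low
            m ^= low
        if not removed:
            return live
        live &= ~removed
    return 0


def peel_after_removal(adj: list[int], kc: int, v: int, k: int) -> int:
    """Maximum k-core of ``kc`` minus vertex ``v``, by targeted cascade.

    Only vertices whose neighborhood lost a member can fall below degree k,
    so the cascade re-examines neighbors of removed vertices rather than
    rescanning the whole set.  Equivalent to ``peel_mask(adj, kc ^ bit, k)``.
    """
    live = kc & ~(1 << v)
    frontier = adj[v] & live
    while frontier:
        removed = 0
        m = frontier
        while m:
            low = m & -m
            u = low.bit_length() - 1
            if (adj[u] & live).bit_count() < k:
                removed |= low
            m ^= low
        if not removed:
            break
        live &= ~removed
        frontier = 0
        m = removed
        while m:
            low = m & -m
            frontier |= adj[low.bit_length() - 1]
            m ^= low
        frontier &= live
    return live


def component_mask(adj: list[int], live: int, start_bit: int) -> int:
    """Connected component of ``live`` containing the vertex of ``start_bit``."""
    comp = start_bit
    frontier = start_bit
    while frontier:
        reach = 0
        m = frontier
        while m:
            low = m & -m
            reach |= adj[low.bit_length() - 1]
            m ^= low
        frontier = reach & live & ~comp
        comp |= frontier
    return comp


def is_kcore_mask(adj: list[int], mask: int, k: int) -> bool:
    """True iff ``mask`` is nonempty and every member has >= k neighbors inside."""
    if not mask:
        return False
    m = mask
    while m:
        low = m & -m
        v = low.bit_length() - 1
        if (adj[v] & mask).bit_count() < k:
            return False
        m ^= low
    return True


def is_minimal_kcore_mask(adj: list[int], mask: int, k: int) -> bool:
    """True iff ``mask`` is a k-core and every single-vertex deletion peels to 0."""
    if not is_kcore_mask(adj, mask, k):
        return False
    m = mask
    while m:
        low = m & -m
        if peel_mask(adj, mask ^ low, k):
            return False
        m ^= low
    return True
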