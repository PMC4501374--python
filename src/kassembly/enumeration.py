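"""Enumeration of all minimal k-cores of an undirected graph.

Three routes are provided:

* :func:`enumerate_minimal_kcores` — the backtracking search, a
  Bron–Kerbosch-style recursion over (kcore, not, candidates) states that
  reports every minimal k-core exactly once.  This is the production path.
* :func:`subset_oracle` — exhaustive scan of all vertex subsets, usable up
  to 20 vertices; the independent correctness oracle.
* :func:`naive_enumerate` — the earlier branching scheme (peel to the
  maximum k-core, branch on every single-vertex deletion), with a visited
  set so that repeated configurations are expanded once; results are
  deduplicated.

The backtracking search maintains a current k-core configuration, a *not*
set of vertices that may no longer be deleted on this branch, and the
candidate vertices whose deletion still leaves a k-core.  A node reports
its configuration when every single-vertex deletion peels to the empty set
(exact minimality).  Otherwise it branches on candidates in ascending order
of induced degree; each child is the peeled maximum k-core of the parent
minus the chosen candidate, and a child that loses a *not* member to the
peel is pruned, since any minimal k-core below it has already been
reported on an earlier branch.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import networkx as nx

from ._bitcore import (
    component_mask,
    full_mask,
    is_minimal_kcore_mask,
    iter_bits,
    masks_from_graph,
    peel_after_removal,
    peel_mask,
)
from .graph_model import GraphValidationError

__all__ = [
    "EnumerationResult",
    "enumerate_minimal_kcores",
    "subset_oracle",
    "naive_enumerate",
]

SUBSET_ORACLE_MAX_VERTICES = 20


@dataclass
class EnumerationResult:
    """Canonical list of minimal k-cores plus search statistics.

    ``cores`` holds each minimal k-core as a sorted vertex tuple, the list
    itself sorted lexicographically, so results from different methods or
    orderings compare equal.  ``stats`` records the graph size, threshold,
    method name, and the number of search-node expansions.
    """

    cores: list[tuple[int, ...]]
    stats: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cores)

    def as_sets(self) -> list[set[int]]:
        return [set(c) for c in self.cores]


def _check_threshold(k: int) -> None:
    if not isinstance(k, int) or isinstance(k, bool) or k < 1:
        raise GraphValidationError(f"threshold k must be an integer >= 1, got {k!r}")


def _canonical(masks: list[int], nodes: list[int]) -> list[tuple[int, ...]]:
    cores = {tuple(nodes[i] for i in iter_bits(m)) for m in masks}
    return sorted(cores)


def _backtrack_masks(adj: list[int], root: int, k: int) -> tuple[list[int], int]:
    """Run the backtracking search below the peeled root; return (cores, expansions)."""
    out: list[int] = []
    if not root:
        return out, 0
    expansions = 0
    bit_count = int.bit_count

    def extend(kc: int, nm: int) -> None:
        nonlocal expansions
        expansions += 1
        # one pass: induced degrees and the mask of critical (degree-k) vertices
        degs: list[tuple[int, int, int]] = []
        low = 0
        m = kc
        while m:
            b = m & -m
            v = b.bit_length() - 1
            dg = bit_count(adj[v] & kc)
            if dg == k:
                low |= b
            degs.append((dg, v, b))
            m ^= b
        if low == kc:
            # k-regular configuration: deleting any vertex cascades through
            # its whole component, so the set is minimal iff connected.
            if component_mask(adj, kc, kc & -kc) == kc:
                out.append(kc)
                return
            minimal = False
        else:
            # minimality: every single-vertex deletion must peel to nothing.
            # Fast path: a vertex with no critical neighbor leaves the k-core
            # kc \ {v} behind, so kc is not minimal.
            minimal = True
            for dg, v, b in degs:
                if adj[v] & kc & low == 0:
                    minimal = False
                    break
                if peel_after_removal(adj, kc, v, k):
                    minimal = False
                    break
            if minimal:
                out.append(kc)
                return
        degs.sort()
        for dg, v, b in degs:
            if nm & b:
                continue
            if adj[v] & kc & low == 0:
                child = kc ^ b
            else:
                child = peel_after_removal(adj, kc, v, k)
            # prune if the peel evicted a not-set member: every minimal
            # k-core below such a child was already reported earlier.
            if child and nm & ~child == 0:
                extend(child, nm)
            nm |= b

    depth_needed = bit_count(root) + 100
    if sys.getrecursionlimit() < depth_needed:
        sys.setrecursionlimit(depth_needed)
    extend(root, 0)
    return out, expansions


def enumerate_minimal_kcores(G: nx.Graph, k: int) -> EnumerationResult:
    """All minimal k-cores of ``G``, each exactly once.

    The search starts from the maximum k-core (every minimal k-core lies
    inside it); an empty maximum k-core yields an empty result.
    """
    _check_threshold(k)
    nodes, adj = masks_from_graph(G)
    root = peel_mask(adj, full_mask(len(nodes)), k)
    masks, expansions = _backtrack_masks(adj, root, k)
    return EnumerationResult(
        cores=_canonical(masks, nodes),
        stats={
            "n": len(nodes),
            "k": k,
            "method": "backtrack",
            "node_expansions": expansions,
        },
    )


def subset_oracle(G: nx.Graph, k: int) -> EnumerationResult:
    """Exhaustive scan of all vertex subsets; guard at 20 vertices.

    A subset qualifies iff it is a k-core and each single-vertex deletion
    peels to the empty set.  Independent of the backtracking search.
    """
    _check_threshold(k)
    n = G.number_of_nodes()
    if n > SUBSET_ORACLE_MAX_VERTICES:
        raise GraphValidationError(
            f"subset oracle is limited to {SUBSET_ORACLE_MAX_VERTICES} vertices "
            f"(got {n}); use enumerate_minimal_kcores instead"
        )
    nodes, adj = masks_from_graph(G)
    found = []
    checked = 0
    for mask in range(1, 1 << n):
        if mask.bit_count() < k + 1:
            continue
        checked += 1
        if is_minimal_kcore_mask(adj, mask, k):
            found.append(mask)
    return EnumerationResult(
        cores=_canonical(found, nodes),
        stats={"n": n, "k": k, "method": "oracle", "node_expansions": checked},
    )


def naive_enumerate(G: nx.Graph, k: int) -> EnumerationResult:
    """Branching baseline: peel, then branch on every single-vertex deletion.

    If the current configuration is itself a minimal k-core it is reported;
    otherwise its maximum k-core is computed and one branch is opened per
    member vertex.  Already-expanded configurations are skipped (without
    that cache the branching revisits the same subproblem factorially many
    times); the final list is deduplicated.
    """
    _check_threshold(k)
    nodes, adj = masks_from_graph(G)
    seen: set[int] = set()
    reported: list[int] = []
    stack = [full_mask(len(nodes))]
    expansions = 0
    while stack:
        mask = stack.pop()
        if not mask or mask in seen:
            continue
        seen.add(mask)
        expansions += 1
        if is_minimal_kcore_mask(adj, mask, k):
            reported.append(mask)
            continue
        core = peel_mask(adj, mask, k)
        if not core:
            continue
        if core != mask and core in seen:
            continue
        seen.add(core)
        if is_minimal_kcore_mask(adj, core, k):
            reported.append(core)
            continue
        for v in iter_bits(core):
            stack.append(core & ~(1 << v))
    return EnumerationResult(
        cores=_canonical(reported, nodes),
        stats={
            "n": len(nodes),
            "k": k,
            "method": "naive",
            "node_expansions": expansions,
        },
    )
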