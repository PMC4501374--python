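"""Graph construction, edge-list I/O and seeded random-graph generators.

Graphs model networks of neurons: a vertex is a neuron and an undirected
edge is a synapse of unit strength.  All public functions operate on
:class:`networkx.Graph` (or :class:`networkx.DiGraph` for the directed
extension) with integer vertex labels; the rest of the package builds on
these containers.

The two generators cover the simulation study's graph models: Bernoulli
(Erdős–Rényi) graphs ``G(n, p)`` and random ``d``-regular graphs drawn by
the configuration/pairing model with rejection of non-simple outcomes,
which samples uniformly from simple ``d``-regular graphs.
"""

from __future__ import annotations

from itertools import combinations
from os import PathLike
from typing import Iterable, Union

import networkx as nx
import numpy as np

__all__ = [
    "GraphValidationError",
    "EdgeListParseError",
    "make_graph",
    "read_edge_list",
    "write_edge_list",
    "read_directed_edge_list",
    "write_directed_edge_list",
    "induced_subgraph",
    "bernoulli_graph",
    "random_regular_graph",
    "is_connected",
]

PathType = Union[str, PathLike]
RngLike = Union[None, int, np.random.Generator, np.random.SeedSequence]


class GraphValidationError(ValueError):
    """An edge or vertex set violates the simple-graph contract."""


class EdgeListParseError(ValueError):
    """An edge-list file could not be parsed; the message carries the line number."""


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def make_graph(n: int, edges: Iterable[tuple[int, int]]) -> nx.Graph:
    """Build a simple undirected graph on vertices ``0..n-1``.

    Edges are deduplicated and symmetrized; self-loops and out-of-range
    endpoints raise :class:`GraphValidationError` naming the offending pair.
    """
    if n < 0:
        raise GraphValidationError(f"vertex count must be non-negative, got {n}")
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for u, v in edges:
        if u == v:
            raise GraphValidationError(f"self-loop ({u}, {v}) is not allowed")
        if not (0 <= u < n) or not (0 <= v < n):
            raise GraphValidationError(
                f"edge ({u}, {v}) has an endpoint outside 0..{n - 1}"
            )
        G.add_edge(int(u), int(v))
    return G


def _parse_edge_lines(path: PathType) -> list[tuple[int, int]]:
    edges: list[tuple[int, int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise EdgeListParseError(
                    f"line {lineno}: expected two vertex ids, got {len(parts)} tokens"
                )
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise EdgeListParseError(
                    f"line {lineno}: non-integer vertex id in {parts!r}"
                ) from exc
            if u == v:
                raise GraphValidationError(f"line {lineno}: self-loop {u} {v}")
            if u < 0 or v < 0:
                raise GraphValidationError(f"line {lineno}: negative vertex id")
            edges.append((u, v))
    return edges


def read_edge_list(path: PathType) -> nx.Graph:
    """Read an undirected graph from a whitespace-separated edge list.

    One ``u v`` pair per line; ``#`` starts a comment.  The vertex set is
    the set of ids appearing in edges (isolated vertices are not
    representable in this format).
    """
    G = nx.Graph()
    G.add_edges_from(_parse_edge_lines(path))
    return G


def write_edge_list(G: nx.Graph, path: PathType) -> None:
    """Write each edge once, smaller endpoint first, sorted — diff-able output."""
    lines = sorted((min(u, v), max(u, v)) for u, v in G.edges())
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in lines:
            fh.write(f"{u} {v}\n")


def read_directed_edge_list(path: PathType) -> nx.DiGraph:
    """Read a directed graph; each line ``u v`` is an arc u→v."""
    D = nx.DiGraph()
    D.add_edges_from(_parse_edge_lines(path))
    return D


def write_directed_edge_list(D: nx.DiGraph, path: PathType) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(D.edges()):
            fh.write(f"{u} {v}\n")


def induced_subgraph(G: nx.Graph, S: Iterable[int]) -> nx.Graph:
    """Return a standalone copy of the subgraph of ``G`` induced by ``S``."""
    S = set(S)
    missing = S - set(G.nodes())
    if missing:
        raise GraphValidationError(
            f"vertices {sorted(missing)} are not in the graph"
        )
    return nx.Graph(G.subgraph(S))


def bernoulli_graph(n: int, p: float, rng: RngLike = None) -> nx.Graph:
    """Sample ``G(n, p)``: each of the C(n,2) pairs is an edge independently.

    Reproducible for a fixed seed or generator.
    """
    if not 0.0 <= p <= 1.0:
        raise GraphValidationError(f"edge probability must lie in [0, 1], got {p}")
    if n < 1:
        raise GraphValidationError(f"need at least one vertex, got n={n}")
    gen = _as_rng(rng)
    pairs = list(combinations(range(n), 2))
    keep = gen.random(len(pairs)) < p
    G = nx.Graph()
    G.add_nodes_from(range(n))
    G.add_edges_from(pair for pair, k in zip(pairs, keep) if k)
    return G


def random_regular_graph(
    n: int, d: int, rng: RngLike = None, max_tries: int = 100_000
) -> nx.Graph:
    """Sample a simple ``d``-regular graph on ``n`` vertices.

    Configuration (pairing) model: shuffle ``n*d`` half-edge stubs, pair them
    consecutively, and reject the whole pairing if it produces a self-loop or
    a repeated edge.  Accepted samples are uniform over simple d-regular
    graphs; for d=5 roughly one pairing in ~400 is accepted, so the retry
    loop is cheap at the studied sizes.
    """
    if d < 0 or d >= max(n, 1):
        raise GraphValidationError(f"degree d={d} must satisfy 0 <= d < n={n}")
    if (n * d) % 2 != 0:
        raise GraphValidationError(f"n*d must be even, got n={n}, d={d}")
    gen = _as_rng(rng)
    if d == 0:
        G = nx.Graph()
        G.add_nodes_from(range(n))
        return G
    stubs = np.repeat(np.arange(n), d)
    for _ in range(max_tries):
        gen.shuffle(stubs)
        seen: set[tuple[int, int]] = set()
        ok = True
        for i in range(0, len(stubs), 2):
            u, v = int(stubs[i]), int(stubs[i + 1])
            if u == v:
                ok = False
                break
            e = (u, v) if u < v else (v, u)
            if e in seen:
                ok = False
                break
            seen.add(e)
        if ok:
            G = nx.Graph()
            G.add_nodes_from(range(n))
            G.add_edges_from(seen)
            return G
    raise RuntimeError(
        f"failed to draw a simple {d}-regular graph on {n} vertices "
        f"after {max_tries} pairings"
    )


def is_connected(G: nx.Graph) -> bool:
    """True iff ``G`` has at most one connected component (empty graph: True)."""
    if G.number_of_nodes() == 0:
        return True
    return nx.is_connected(G)
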