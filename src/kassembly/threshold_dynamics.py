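"""Threshold activation dynamics: the calculus behind cell assemblies.

A set ``S`` of active neurons excites, in one synchronous step, every
vertex with at least ``k`` active neighbors:

    f_k(S) = { v in V : |N(v) ∩ S| >= k }.

Membership in ``S`` is *not* retained by fiat — an active vertex with fewer
than ``k`` active neighbors drops out at the next step.  Iterating f_k
either reaches a fixed point (the *closure* of ``S``), dies out at the
empty set (``S`` is *weak*), or enters a nontrivial cycle, in which case
the closure is undefined.  A *k-assembly* is the closure of a minimal
k-core: the memory pattern ignited by exciting that minimal substructure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import networkx as nx

from .graph_model import GraphValidationError
from .kcore_algorithms import is_minimal_kcore

__all__ = [
    "ClosureUndefinedError",
    "DynamicsTrace",
    "threshold_step",
    "iterate",
    "closure",
    "is_invariant",
    "is_persistent",
    "is_weak",
    "k_assembly",
]


class ClosureUndefinedError(RuntimeError):
    """Raised when iteration cycles without reaching a fixed point.

    Carries the offending trace as the ``trace`` attribute.
    """

    def __init__(self, message: str, trace: "DynamicsTrace"):
        super().__init__(message)
        self.trace = trace


@dataclass
class DynamicsTrace:
    """The iteration record: states[0] = S, states[i] = f_k^i(S).

    ``status`` is ``"fixed_point"`` when the last two states are equal and
    nonempty, ``"empty"`` when the trajectory reaches the empty set, and
    ``"cycle"`` when a state other than the previous one recurs;
    ``cycle_start`` is then the index of its first occurrence.
    """

    states: list[frozenset[int]]
    status: Literal["fixed_point", "empty", "cycle"]
    cycle_start: Optional[int] = None

    @property
    def final(self) -> frozenset[int]:
        return self.states[-1]


def _check_subset(G: nx.Graph, S: Iterable[int]) -> frozenset[int]:
    S = frozenset(S)
    missing = S - set(G.nodes())
    if missing:
        raise GraphValidationError(f"vertices {sorted(missing)} are not in the graph")
    return S


def _check_threshold(k: int) -> None:
    if not isinstance(k, int) or isinstance(k, bool) or k < 1:
        raise GraphValidationError(f"threshold k must be an integer >= 1, got {k!r}")


def threshold_step(G: nx.Graph, S: Iterable[int], k: int) -> frozenset[int]:
    """One synchronous update: the set of vertices with >= k active neighbors."""
    _check_threshold(k)
    S = _check_subset(G, S)
    return frozenset(
        v for v in G.nodes() if sum(1 for u in G[v] if u in S) >= k
    )


def iterate(
    G: nx.Graph, S: Iterable[int], k: int, max_steps: Optional[int] = None
) -> DynamicsTrace:
    """Apply ``threshold_step`` until a fixed point, the empty set, or a revisit.

    Termination is guaranteed by revisit detection (state space is finite).
    ``max_steps`` is a safety valve only; exceeding it raises RuntimeError.
    """
    _check_threshold(k)
    state = _check_subset(G, S)
    states = [state]
    seen = {state: 0}
    step = 0
    while True:
        if max_steps is not None and step >= max_steps:
            raise RuntimeError(
                f"iteration exceeded max_steps={max_steps} without terminating; "
                "pass max_steps=None to rely on revisit detection"
            )
        nxt = threshold_step(G, state, k)
        states.append(nxt)
        step += 1
        if nxt == state:
            status = "empty" if not nxt else "fixed_point"
            return DynamicsTrace(states=states, status=status)
        if nxt in seen:
            return DynamicsTrace(states=states, status="cycle", cycle_start=seen[nxt])
        seen[nxt] = len(states) - 1
        state = nxt


def closure(G: nx.Graph, S: Iterable[int], k: int) -> frozenset[int]:
    """The invariant set f_k^n(S) reached when f_k^n(S) = f_k^{n-1}(S).

    A weak set's closure is the empty set.  If the trajectory cycles without
    a fixed point the closure does not exist and
    :class:`ClosureUndefinedError` is raised with the trace attached.
    """
    trace = iterate(G, S, k)
    if trace.status == "cycle":
        raise ClosureUndefinedError(
            "closure undefined for this set: iteration entered a cycle "
            f"(first revisited state at index {trace.cycle_start})",
            trace,
        )
    return trace.final


def is_invariant(G: nx.Graph, S: Iterable[int], k: int) -> bool:
    """True iff f_k(S) = S (a self-sustaining activation pattern)."""
    S = frozenset(S)
    return threshold_step(G, S, k) == S


def is_persistent(G: nx.Graph, S: Iterable[int], k: int) -> bool:
    """True iff S ⊆ f_k(S): activation never loses members."""
    S = frozenset(S)
    return S <= threshold_step(G, S, k)


def is_weak(G: nx.Graph, S: Iterable[int], k: int) -> bool:
    """True iff some iterate of f_k maps S to the empty set."""
    return iterate(G, S, k).status == "empty"


def k_assembly(G: nx.Graph, M: Iterable[int], k: int) -> frozenset[int]:
    """The k-assembly ignited by a minimal k-core ``M``: its closure.

    ``M`` must be a minimal k-core of ``G``; the result is invariant and
    contains ``M``.
    """
    M = frozenset(M)
    if not is_minimal_kcore(G, M, k):
        raise GraphValidationError(
            f"{sorted(M)} is not a minimal {k}-core of the graph"
        )
    return closure(G, M, k)
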