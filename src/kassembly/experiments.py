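"""Seeded replication harness for the random-graph simulation study.

For each replicate a graph is drawn from the configured model (Bernoulli
G(n, p) or random d-regular), its minimal k-cores are enumerated for every
requested threshold, and the per-threshold counts are aggregated with the
*conditional mean* convention: the mean number of minimal k-cores is taken
over the replicates that contained at least one (zero-core replicates are
counted separately, not averaged in).

Replicate streams are spawned from a single seed via
:class:`numpy.random.SeedSequence`, so a (config, seed) pair reproduces the
same graphs, counts and CSV bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import enumeration
from .graph_model import GraphValidationError, bernoulli_graph, random_regular_graph

__all__ = [
    "ExperimentConfig",
    "KSummaryRow",
    "ExperimentSummary",
    "OverlapReport",
    "run_experiment",
    "overlap_stats",
    "write_summary_csv",
    "write_overlap_csv",
]

_METHODS: dict[str, Callable[[nx.Graph, int], enumeration.EnumerationResult]] = {
    "backtrack": enumeration.enumerate_minimal_kcores,
    "oracle": enumeration.subset_oracle,
    "naive": enumeration.naive_enumerate,
}


@dataclass
class ExperimentConfig:
    """One test instance: a graph model, thresholds, replicate count, seed."""

    model: str  # "bernoulli" or "regular"
    n: int
    k_values: Sequence[int]
    p: Optional[float] = None  # bernoulli edge probability
    d: Optional[int] = None  # regular degree
    replicates: int = 100
    seed: int = 0
    method: str = "backtrack"

    def __post_init__(self) -> None:
        if self.model not in ("bernoulli", "regular"):
            raise GraphValidationError(
                f"model must be 'bernoulli' or 'regular', got {self.model!r}"
            )
        if self.model == "bernoulli" and self.p is None:
            raise GraphValidationError("bernoulli model requires p")
        if self.model == "regular" and self.d is None:
            raise GraphValidationError("regular model requires d")
        if self.replicates < 1:
            raise GraphValidationError("replicates must be >= 1")
        if not self.k_values or any(k < 1 for k in self.k_values):
            raise GraphValidationError("k_values must be a nonempty list of k >= 1")
        if self.method not in _METHODS:
            raise GraphValidationError(
                f"method must be one of {sorted(_METHODS)}, got {self.method!r}"
            )

    @property
    def model_label(self) -> str:
        if self.model == "bernoulli":
            return f"bernoulli(n={self.n}, p={self.p})"
        return f"regular(n={self.n}, d={self.d})"


@dataclass
class KSummaryRow:
    """Aggregate for one threshold k within an experiment."""

    k: int
    replicates: int
    graphs_with_core: int
    conditional_mean_count: float
    sd_count: float
    total_cores: int
    counts: tuple[int, ...]  # per-replicate minimal-k-core counts

    @property
    def standard_error(self) -> float:
        """SE of the conditional mean, from the nonzero-count replicates."""
        if self.graphs_with_core < 2:
            return float("nan")
        return self.sd_count / math.sqrt(self.graphs_with_core)


@dataclass
class ExperimentSummary:
    config: ExperimentConfig
    rows: list[KSummaryRow] = field(default_factory=list)

    def row(self, k: int) -> KSummaryRow:
        for r in self.rows:
            if r.k == k:
                return r
        raise KeyError(f"no summary row for k={k}")


def _replicate_graphs(config: ExperimentConfig) -> Iterable[nx.Graph]:
    streams = np.random.SeedSequence(config.seed).spawn(config.replicates)
    for ss in streams:
        rng = np.random.default_rng(ss)
        if config.model == "bernoulli":
            yield bernoulli_graph(config.n, config.p, rng)
        else:
            yield random_regular_graph(config.n, config.d, rng)


def run_experiment(config: ExperimentConfig) -> ExperimentSummary:
    """Generate replicate graphs and aggregate minimal-k-core counts per k."""
    method = _METHODS[config.method]
    counts: dict[int, list[int]] = {k: [] for k in config.k_values}
    for G in _replicate_graphs(config):
        for k in config.k_values:
            counts[k].append(len(method(G, k).cores))
    rows = []
    for k in config.k_values:
        arr = np.asarray(counts[k])
        nonzero = arr[arr > 0]
        mean = float(nonzero.mean()) if nonzero.size else 0.0
        sd = float(nonzero.std(ddof=1)) if nonzero.size > 1 else 0.0
        rows.append(
            KSummaryRow(
                k=k,
                replicates=config.replicates,
                graphs_with_core=int(nonzero.size),
                conditional_mean_count=mean,
                sd_count=sd,
                total_cores=int(arr.sum()),
                counts=tuple(int(c) for c in arr),
            )
        )
    return ExperimentSummary(config=config, rows=rows)


@dataclass
class OverlapReport:
    """How the minimal k-cores of one graph share vertices.

    ``pairwise_jaccard[i, j]`` is |core_i ∩ core_j| / |core_i ∪ core_j|;
    ``membership_count[v]`` is the number of cores containing vertex v;
    ``shared_fraction`` is the fraction of the graph's vertices lying in at
    least two cores.
    """

    cores: list[tuple[int, ...]]
    pairwise_jaccard: np.ndarray
    membership_count: dict[int, int]
    shared_fraction: float


def overlap_stats(result: enumeration.EnumerationResult, G: nx.Graph) -> OverlapReport:
    """Pairwise Jaccard overlaps and per-vertex core membership counts."""
    cores = [frozenset(c) for c in result.cores]
    m = len(cores)
    jac = np.zeros((m, m))
    for i in range(m):
        jac[i, i] = 1.0
        for j in range(i + 1, m):
            inter = len(cores[i] & cores[j])
            union = len(cores[i] | cores[j])
            jac[i, j] = jac[j, i] = inter / union
    membership = {v: 0 for v in sorted(G.nodes())}
    for core in cores:
        for v in core:
            membership[v] += 1
    n = G.number_of_nodes()
    shared = sum(1 for v, c in membership.items() if c >= 2) / n if n else 0.0
    return OverlapReport(
        cores=list(result.cores),
        pairwise_jaccard=jac,
        membership_count=membership,
        shared_fraction=shared,
    )


def summary_frame(summary: ExperimentSummary) -> pd.DataFrame:
    cfg = summary.config
    records = []
    for r in summary.rows:
        records.append(
            {
                "model": cfg.model,
                "n": cfg.n,
                "param": cfg.p if cfg.model == "bernoulli" else cfg.d,
                "k": r.k,
                "replicates": r.replicates,
                "graphs_with_core": r.graphs_with_core,
                "conditional_mean_count": r.conditional_mean_count,
                "sd_count": r.sd_count,
                "total_cores": r.total_cores,
            }
        )
    columns = [
        "model",
        "n",
        "param",
        "k",
        "replicates",
        "graphs_with_core",
        "conditional_mean_count",
        "sd_count",
        "total_cores",
    ]
    return pd.DataFrame.from_records(records, columns=columns)


def write_summary_csv(summary: ExperimentSummary, path) -> None:
    """One row per threshold k; byte-identical for identical (config, seed)."""
    summary_frame(summary).to_csv(path, index=False)


def write_overlap_csv(report: OverlapReport, path) -> None:
    """One row per vertex: membership count and whether the vertex is shared."""
    df = pd.DataFrame(
        {
            "vertex": list(report.membership_count.keys()),
            "membership_count": list(report.membership_count.values()),
        }
    )
    df["shared"] = (df["membership_count"] >= 2).astype(int)
    df.to_csv(path, index=False)
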