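"""Ensemble Louvain community detection on the co-expression graph.

The graph is clustered many times (10,000 runs by default) with the
two-phase "fast unfolding" (Louvain) heuristic under different random
node orders, the 100 best partitions by weighted Newman–Girvan modularity
are kept, and a final partition is chosen either as the modularity maximum
or as the most informative by gene-signature enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .enrichment import NEGLOG10_FLOOR, enrich_modules
from .io import SignatureDatabase
from .network import CorrelationGraph

__all__ = ["Partition", "EnsembleResult", "modularity", "louvain_run", "cluster_ensemble", "select_partition"]

DEFAULT_N_RUNS = 10_000
DEFAULT_KEEP = 100
DEFAULT_BASE_SEED = 42


@dataclass
class Partition:
    """Gene → module assignment with its modularity score Q.

    Module labels are "M1", "M2", … ordered by descending module size
    (ties by the lexicographically smallest member gene).
    """

    assignment: dict[str, str]
    modularity: float
    seed: int | None = None

    def modules(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, label in self.assignment.items():
            out.setdefault(label, set()).add(gene)
        return out

    def labels(self) -> list[str]:
        return sorted(self.modules(), key=lambda m: int(m[1:]))

    def __len__(self) -> int:
        return len(set(self.assignment.values()))


@dataclass
class EnsembleResult:
    """Best partitions of a clustering ensemble, Q non-increasing."""

    partitions: list[Partition]
    n_runs: int
    kept: int = field(init=False)
    base_seed: int = DEFAULT_BASE_SEED

    def __post_init__(self) -> None:
        self.kept = len(self.partitions)
        qs = [p.modularity for p in self.partitions]
        if any(a < b for a, b in zip(qs, qs[1:])):
            raise ValueError("ensemble partitions must be ordered by non-increasing Q")

    @property
    def best(self) -> Partition:
        return self.partitions[0]


def _graph_of(graph: CorrelationGraph | nx.Graph) -> nx.Graph:
    return graph.graph if isinstance(graph, CorrelationGraph) else graph


def modularity(graph: CorrelationGraph | nx.Graph, partition: Partition | dict[str, str]) -> float:
    """Weighted Newman–Girvan modularity.

    Q = (1/2W) Σ_ij [w_ij − s_i s_j / 2W] δ(c_i, c_j) with W the total edge
    weight and s_i the weighted degree of node i.
    """
    g = _graph_of(graph)
    assignment = partition.assignment if isinstance(partition, Partition) else partition
    missing = [v for v in g.nodes if v not in assignment]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:10]}")
    two_w = sum(d.get("weight", 1.0) for _, _, d in g.edges(data=True)) * 2.0
    if two_w == 0:
        raise ValueError("graph has zero total edge weight")
    strength: dict[str, float] = {v: 0.0 for v in g.nodes}
    within: dict[str, float] = {}
    for a, b, d in g.edges(data=True):
        w = d.get("weight", 1.0)
        strength[a] += w
        strength[b] += w
        if assignment[a] == assignment[b]:
            within[assignment[a]] = within.get(assignment[a], 0.0) + w
    q = 0.0
    strength_per_module: dict[str, float] = {}
    for v, s in strength.items():
        c = assignment[v]
        strength_per_module[c] = strength_per_module.get(c, 0.0) + s
    for c, s_c in strength_per_module.items():
        q += within.get(c, 0.0) / (two_w / 2.0) - (s_c / two_w) ** 2
    return q


def _canonical_labels(communities, graph: nx.Graph) -> dict[str, str]:
    """Relabel communities M1… by descending size, ties by smallest member."""
    comms = sorted(
        (sorted(c) for c in communities),
        key=lambda members: (-len(members), members[0]),
    )
    assignment: dict[str, str] = {}
    for idx, members in enumerate(comms, start=1):
        for node in members:
            assignment[node] = f"M{idx}"
    missing = [v for v in graph.nodes if v not in assignment]
    for node in sorted(missing):
        assignment[node] = f"M{len(comms) + 1}"
        comms.append([node])
    return assignment


def louvain_run(graph: CorrelationGraph | nx.Graph, seed: int) -> Partition:
    """One seeded Louvain clustering; deterministic given (graph, seed)."""
    g = _graph_of(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if g.number_of_edges() == 0:
        assignment = _canonical_labels([[v] for v in g.nodes], g)
        return Partition(assignment=assignment, modularity=0.0, seed=seed)
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=1.0, seed=int(seed)
    )
    assignment = _canonical_labels(communities, g)
    return Partition(assignment=assignment, modularity=modularity(g, assignment), seed=seed)


def cluster_ensemble(
    graph: CorrelationGraph | nx.Graph,
    n_runs: int = DEFAULT_N_RUNS,
    keep: int = DEFAULT_KEEP,
    base_seed: int = DEFAULT_BASE_SEED,
) -> EnsembleResult:
    """Run Louvain with seeds base_seed…base_seed+n_runs−1, keep the best.

    Partitions are ranked by Q descending with ties broken by run index,
    so the result is reproducible from base_seed alone.
    """
    if keep > n_runs:
        raise ValueError("keep must not exceed n_runs")
    runs = [louvain_run(graph, base_seed + i) for i in range(n_runs)]
    order = sorted(range(n_runs), key=lambda i: (-runs[i].modularity, i))
    partitions = [runs[i] for i in order[:keep]]
    return EnsembleResult(partitions=partitions, n_runs=n_runs, base_seed=base_seed)


def _enrichment_informativeness(
    partition: Partition, signatures: SignatureDatabase, population: set[str]
) -> float:
    """Σ over modules of −log10(best signature FDR), floored at 1e−300."""
    table = enrich_modules(
        partition, signatures, population, fdr_threshold=1.0 + 1e-9, top=1
    ).table
    score = 0.0
    for _, row in table.iterrows():
        score += -np.log10(max(float(row["fdr"]), NEGLOG10_FLOOR))
    return score


def select_partition(
    ensemble: EnsembleResult,
    strategy: str = "max_modularity",
    signatures: SignatureDatabase | None = None,
    population: set[str] | None = None,
) -> Partition:
    """Pick the final partition from the kept ensemble.

    "max_modularity" returns the top partition.  "enrichment" scores each
    kept partition by the summed −log10 best-signature FDR over its
    modules and returns the argmax (ties → higher Q, then earlier run).
    """
    if not ensemble.partitions:
        raise ValueError("empty ensemble")
    if strategy == "max_modularity":
        return ensemble.best
    if strategy == "enrichment":
        if signatures is None or population is None:
            raise ValueError("enrichment strategy requires signatures and a population")
        best, best_key = None, None
        for idx, part in enumerate(ensemble.partitions):
            score = _enrichment_informativeness(part, signatures, population)
            key = (score, part.modularity, -idx)
            if best_key is None or key > best_key:
                best, best_key = part, key
        return best
    raise ValueError(f"unknown strategy: {strategy}")
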