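"""Sparsified, symmetrized Spearman co-expression networks.

This is the parsimonious core of PGCNA: all n(n−1)/2 pairwise Spearman
rank correlations are computed, then for every gene only its k most
positively correlated partners are retained (k = 3 by default), and the
resulting edge matrix M is symmetrized (m_ij = m_ji), i.e. the final edge
set is the union over genes of their per-gene top-k lists.  For n = 9,063
genes this reduces 41,064,453 candidate pairs to a graph of a few tens of
thousands of edges on which modularity clustering is well conditioned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .selection import GeneMatrix

__all__ = ["CorrelationGraph", "pair_count", "spearman_all_pairs", "retain_topk_edges", "build_network"]

logger = logging.getLogger(__name__)


def pair_count(n_genes: int) -> int:
    """Distinct gene pairs evaluated by the correlation stage: n(n−1)/2."""
    return n_genes * (n_genes - 1) // 2


@dataclass
class CorrelationGraph:
    """Weighted, symmetric co-expression graph with stage counters."""

    graph: nx.Graph
    k: int
    n_genes: int
    n_pairs_total: int
    n_edges_retained: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_edges_retained = self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_bounds(self) -> tuple[int, int]:
        """[ceil(k·n/2), k·n] bound on retained edges when every node has
        at least k positive partners."""
        return (-(-self.k * self.n_genes // 2), self.k * self.n_genes)


def spearman_all_pairs(genes: GeneMatrix | pd.DataFrame) -> pd.DataFrame:
    """All-pairs Spearman ρ between gene rows (average ranks on ties).

    Constant rows have undefined ρ and are dropped with a warning before
    the correlation is computed.
    """
    values = genes.values if isinstance(genes, GeneMatrix) else genes
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    data = values.to_numpy(dtype=float)
    constant = np.ptp(data, axis=1) == 0
    if constant.any():
        dropped = list(values.index[constant])
        logger.warning("dropping %d constant gene rows: %s", len(dropped), dropped[:5])
        values = values.loc[~constant]
        data = data[~constant]
    if len(values) < 2:
        raise ValueError("fewer than 2 non-constant genes")
    # rank rows, then Pearson on ranks == Spearman with average-rank ties
    ranks = stats.rankdata(data, axis=1)
    rho = np.corrcoef(ranks)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=values.index, columns=values.index)


def retain_topk_edges(rho: pd.DataFrame, k: int = 3, use_absolute: bool = False) -> CorrelationGraph:
    """Keep each gene's k strongest partners and symmetrize.

    Partners are ranked by ρ descending among strictly positive ρ (or by
    |ρ| when ``use_absolute``), ties at the k-th rank broken by
    lexicographic partner id; the edge set is the union over genes, so a
    pair survives if either endpoint nominated it.  Genes with no positive
    partner remain as isolated nodes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    names = list(rho.index)
    n = len(names)
    if k >= n:
        logger.info("k=%d >= n=%d: retaining all positive edges", k, n)
    mat = rho.to_numpy(dtype=float).copy()
    if use_absolute:
        score = np.abs(mat)
    else:
        score = mat
    np.fill_diagonal(score, -np.inf)

    graph = nx.Graph()
    graph.add_nodes_from(names)
    # rank of each column id in lexicographic order, for deterministic ties
    lex_rank = np.empty(n, dtype=np.int64)
    lex_rank[np.argsort(np.asarray(names, dtype=object), kind="stable")] = np.arange(n)
    for i in range(n):
        row = score[i]
        eligible = np.flatnonzero(row > 0)
        if eligible.size == 0:
            continue
        # primary key: score descending; ties: lexicographically smaller id
        order = eligible[np.lexsort((lex_rank[eligible], -row[eligible]))]
        for j in order[:k]:
            a, b = names[i], names[j]
            w = float(mat[i, j])
            if graph.has_edge(a, b):
                # symmetric input: same weight from either direction
                continue
            graph.add_edge(a, b, weight=w)
    return CorrelationGraph(graph=graph, k=k, n_genes=n, n_pairs_total=pair_count(n))


def build_network(genes: GeneMatrix, k: int = 3, use_absolute: bool = False) -> CorrelationGraph:
    """Convenience: correlation matrix then top-k retention in one call."""
    return retain_topk_edges(spearman_all_pairs(genes), k=k, use_absolute=use_absolute)
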