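"""Overlap statistics between module sets and differential-expression sets.

All overlaps reduce to one hypergeometric upper-tail kernel: the overlap of
two sets is tested against random draws from a shared population, and the
matrix of −log10 p values is what the heatmap figures display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import Partition
from .enrichment import EnrichmentTable, hypergeom_upper_tail, neg_log10

__all__ = [
    "OverlapMatrix",
    "DESet",
    "module_overlap_matrix",
    "signature_overlap_matrix",
    "de_overlap_heatmap",
    "venn_partition",
]


@dataclass
class OverlapMatrix:
    """−log10 hypergeometric p values plus raw overlap counts."""

    neg_log10_p: pd.DataFrame
    counts: pd.DataFrame

    @property
    def shape(self) -> tuple[int, int]:
        return self.neg_log10_p.shape


@dataclass
class DESet:
    """One differential-expression gene set of the time-course design."""

    condition: str
    timepoint: str
    direction: str  # "induced" or "repressed"
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.direction not in ("induced", "repressed"):
            raise ValueError(f"direction must be induced/repressed, got {self.direction}")

    @property
    def label(self) -> str:
        return f"{self.condition}:{self.timepoint}"


def _overlap_grid(
    row_sets: dict[str, set[str]], col_sets: dict[str, set[str]], population_size: int
) -> OverlapMatrix:
    if population_size <= 0:
        raise ValueError("population must be non-empty")
    rows, cols = list(row_sets), list(col_sets)
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    logp = np.zeros((len(rows), len(cols)), dtype=float)
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            k = len(row_sets[r] & col_sets[c])
            counts[i, j] = k
            p = hypergeom_upper_tail(
                k, len(row_sets[r]), len(col_sets[c]), population_size
            )
            logp[i, j] = float(neg_log10(p))
    return OverlapMatrix(
        neg_log10_p=pd.DataFrame(logp, index=rows, columns=cols),
        counts=pd.DataFrame(counts, index=rows, columns=cols),
    )


def module_overlap_matrix(
    part_a: Partition, part_b: Partition, population: set[str]
) -> OverlapMatrix:
    """Gene-level module overlap between two networks' partitions.

    Entry (i, j) is −log10 P(X ≥ |Mi ∩ Mj|) for a hypergeometric draw of
    |Mi| genes from the shared population containing |Mj| successes.
    """
    mods_a, mods_b = part_a.modules(), part_b.modules()
    for mods in (mods_a, mods_b):
        stray = set().union(*mods.values()) - population
        if stray:
            raise ValueError(f"module genes outside population: {sorted(stray)[:5]}")
    ordered_a = {m: mods_a[m] for m in part_a.labels()}
    ordered_b = {m: mods_b[m] for m in part_b.labels()}
    return _overlap_grid(ordered_a, ordered_b, len(population))


def signature_overlap_matrix(
    enrich_a: EnrichmentTable,
    enrich_b: EnrichmentTable,
    signature_universe: int | None = None,
    p_threshold: float = 0.001,
    min_size: int = 5,
    max_size: int = 1000,
) -> OverlapMatrix:
    """Signature-level module overlap between two networks.

    Each module is represented by the set of signature names it enriches
    after the prefilter (raw p < 0.001, signature size 5–1000), and those
    name sets are compared hypergeometrically against the filtered
    signature universe (by default: signatures surviving the prefilter in
    either table).
    """
    sig_a = enrich_a.significant_signatures(p_threshold, min_size, max_size)
    sig_b = enrich_b.significant_signatures(p_threshold, min_size, max_size)
    if signature_universe is None:
        universe = set().union(*sig_a.values(), *sig_b.values()) if (sig_a or sig_b) else set()
        signature_universe = len(universe)
    if signature_universe <= 0:
        raise ValueError("signature universe is empty")
    return _overlap_grid(sig_a, sig_b, signature_universe)


def de_overlap_heatmap(sets: list[DESet], population: set[str]) -> OverlapMatrix:
    """All-by-all overlap of DE sets of a single direction.

    This is the data behind the pairwise convergence heatmaps: each
    (condition, timepoint) DE set is compared with every other and the
    significance of the overlap reported as −log10 p.
    """
    directions = {s.direction for s in sets}
    if len(directions) > 1:
        raise ValueError("mix of induced and repressed sets; compare one direction at a time")
    named = {s.label: set(s.genes) for s in sets}
    if len(named) != len(sets):
        raise ValueError("duplicate (condition, timepoint) labels")
    return _overlap_grid(named, named, len(population))


def venn_partition(
    set_a: set[str], set_b: set[str], set_c: set[str]
) -> dict[str, int]:
    """Counts of the 7 exclusive regions of a three-way Venn diagram."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    return {
        "A": len(a - b - c),
        "B": len(b - a - c),
        "C": len(c - a - b),
        "AB": len((a & b) - c),
        "AC": len((a & c) - b),
        "BC": len((b & c) - a),
        "ABC": len(a & b & c),
    }
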