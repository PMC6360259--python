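"""Informative-probe selection and probe→gene merging.

Probes enter the network stage only if they are differentially expressed in
at least one of the configured contrasts (Welch t-test on log2 values plus
a linear fold-change cut) or vary across the design (variance of the
per-(condition, timepoint) donor medians above a threshold).  Selected
probes are then collapsed to one row per gene, keeping the most variable
probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr
from .io import ExpressionMatrix

__all__ = [
    "SelectionConfig",
    "GeneMatrix",
    "welch_t_test",
    "differential_probes",
    "variance_filter",
    "select_informative",
    "merge_probes_to_genes",
]


@dataclass
class SelectionConfig:
    """Thresholds for probe selection / differential-expression calling.

    Defaults are the long-time-course selection settings (p < 0.01,
    fold change > 1.2, variance of group medians > 0.05 on the log2
    scale).  DE-set mode (fold change > 1.5 with BH-adjusted p < 0.05)
    is obtained with ``de_p_threshold=0.05, de_fc_threshold=1.5,
    de_adjust=True``.
    """

    de_p_threshold: float = 0.01
    de_fc_threshold: float = 1.2
    de_adjust: bool = False
    variance_threshold: float = 0.05
    contrasts: list[tuple[list[str], list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.de_p_threshold <= 0 or self.variance_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.de_fc_threshold <= 1:
            raise ValueError("fold-change threshold must exceed 1")
        for a, b in self.contrasts:
            if not a or not b:
                raise ValueError("contrast groups must be non-empty")
            if set(a) & set(b):
                raise ValueError("contrast groups must be disjoint")


@dataclass
class GeneMatrix:
    """Gene-level log2 matrix after probe merging.

    ``provenance`` records which probe represents each gene.
    """

    values: pd.DataFrame  # genes x samples
    samples: pd.DataFrame
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene rows after merge")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("gene matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch two-sample t-test; returns (t, Welch–Satterthwaite df, two-sided p).

    Both groups constant with equal means is not evidence of change:
    returns t=0, p=1 rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in test input")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        return math.copysign(math.inf, x.mean() - y.mean()), float(x.size + y.size - 2), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    sx, sy = vx / x.size, vy / y.size
    denom = sx**2 / (x.size - 1) + sy**2 / (y.size - 1)
    # denominator can underflow for near-constant groups; pooled df fallback
    df = (sx + sy) ** 2 / denom if denom > 0 else float(x.size + y.size - 2)
    return float(t), float(df), float(p)


def _welch_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch p values for matrices a (probes x nA) and b (probes x nB)."""
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # constant rows in both groups: scipy yields nan; equal means -> p=1, else 0
    bad = ~np.isfinite(p)
    if bad.any():
        equal = np.isclose(a[bad].mean(axis=1), b[bad].mean(axis=1))
        p[bad] = np.where(equal, 1.0, 0.0)
    return p


def differential_probes(
    matrix: ExpressionMatrix,
    contrast: tuple[list[str], list[str]],
    config: SelectionConfig,
) -> tuple[set[str], set[str]]:
    """Up- and down-regulated probe sets for one contrast (A vs B).

    A probe is "up" iff mean(A) − mean(B) > log2(fc threshold) (strict) and
    its (optionally BH-adjusted, across probes of this contrast) Welch p is
    below the p threshold; "down" is symmetric.
    """
    group_a, group_b = contrast
    if not group_a or not group_b:
        raise ValueError("empty contrast group")
    a = matrix.values[list(group_a)].to_numpy(dtype=float)
    b = matrix.values[list(group_b)].to_numpy(dtype=float)
    delta = a.mean(axis=1) - b.mean(axis=1)
    p = _welch_rows(a, b)
    if config.de_adjust:
        p = np.asarray(bh_fdr(p))
    log_fc = math.log2(config.de_fc_threshold)
    sig = p < config.de_p_threshold
    probes = np.asarray(matrix.probe_ids)
    up = set(probes[sig & (delta > log_fc)])
    down = set(probes[sig & (delta < -log_fc)])
    return up, down


def variance_filter(matrix: ExpressionMatrix, config: SelectionConfig) -> set[str]:
    """Probes whose per-group (condition × timepoint) donor medians vary.

    For each probe the median across donors is taken within every group,
    and the unbiased variance of those medians must strictly exceed the
    threshold.
    """
    groups = matrix.groups()
    if len(groups) < 2:
        raise ValueError("variance filter needs at least 2 (condition, timepoint) groups")
    medians = np.column_stack(
        [
            np.median(matrix.values[matrix.group_samples(c, t)].to_numpy(dtype=float), axis=1)
            for c, t in groups
        ]
    )
    var = medians.var(axis=1, ddof=1)
    probes = np.asarray(matrix.probe_ids)
    return set(probes[var > config.variance_threshold])


def select_informative(
    de_results: list[tuple[set[str], set[str]]], variance_set: set[str]
) -> set[str]:
    """Nonredundant union of all DE probes (any contrast, either direction)
    and the variance-passing probes."""
    selected = set(variance_set)
    for up, down in de_results:
        selected |= up
        selected |= down
    return selected


def merge_probes_to_genes(
    matrix: ExpressionMatrix, selected: set[str], annotation: dict[str, str]
) -> GeneMatrix:
    """Collapse selected probes to one row per gene.

    Unannotated probes are dropped.  Where several selected probes map to
    one gene, the probe with the largest variance across all samples is
    kept; ties go to the lexicographically smaller probe id.
    """
    if not selected:
        raise ValueError("empty probe selection")
    unknown = selected - set(matrix.probe_ids)
    if unknown:
        raise ValueError(f"selected probes absent from matrix: {sorted(unknown)[:10]}")
    sub = matrix.values.loc[sorted(selected)]
    variances = sub.var(axis=1, ddof=1)
    best: dict[str, str] = {}
    for probe in sub.index:
        gene = annotation.get(probe)
        if not gene:
            continue
        incumbent = best.get(gene)
        if incumbent is None or variances[probe] > variances[incumbent]:
            best[gene] = probe
    genes = sorted(best)
    values = sub.loc[[best[g] for g in genes]]
    values.index = pd.Index(genes, name="gene")
    return GeneMatrix(values=values, samples=matrix.samples.copy(), provenance=best)
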