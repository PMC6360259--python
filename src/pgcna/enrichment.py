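"""Hypergeometric gene-signature enrichment of network modules.

The test follows the over-representation convention: the draw is the gene
list (module), the successes are the signature genes, and the population is
the genes present on the platform.  P values are BH-corrected across the
whole module × signature family of a run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SignatureDatabase

__all__ = ["EnrichmentTable", "hypergeom_upper_tail", "hypergeom_lower_tail", "bh_fdr", "enrich_modules"]

NEGLOG10_FLOOR = 1e-300  # p floor before -log10, keeps heatmap values finite


@dataclass
class EnrichmentTable:
    """Per-module signature enrichment results."""

    table: pd.DataFrame
    # columns: module, signature, overlap, module_size, signature_size,
    #          population_size, p_value, fdr, direction, neg_log10_fdr

    def significant_signatures(
        self, p_threshold: float = 0.001, min_size: int = 5, max_size: int = 1000
    ) -> dict[str, set[str]]:
        """Signature name sets per module after the overlap-analysis
        prefilter (raw p below threshold, signature size within bounds)."""
        t = self.table
        keep = (
            (t["p_value"] < p_threshold)
            & (t["signature_size"] >= min_size)
            & (t["signature_size"] <= max_size)
            & (t["direction"] == "enriched")
        )
        out: dict[str, set[str]] = {m: set() for m in t["module"].unique()}
        for module, signature in zip(t.loc[keep, "module"], t.loc[keep, "signature"]):
            out[module].add(signature)
        return out


def _check_hypergeom_args(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"overlap k={k} outside [0, min(n={n}, K={K})]")
    if n > N or K > N:
        raise ValueError(f"draw n={n} / successes K={K} exceed population N={N}")


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population N, successes K, draws n)."""
    _check_hypergeom_args(k, n, K, N)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_lower_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X <= k); used for depletion calls."""
    _check_hypergeom_args(k, n, K, N)
    return float(stats.hypergeom.cdf(k, N, K, n))


def bh_fdr(pvalues) -> list[float]:
    """Benjamini–Hochberg step-up q values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def neg_log10(p: float | np.ndarray, cap: float = 300.0):
    """-log10(p) floored at 0 and capped for output stability."""
    return np.minimum(-np.log10(np.maximum(p, NEGLOG10_FLOOR)), cap)


def enrich_modules(
    partition,
    signatures: SignatureDatabase,
    population: set[str],
    min_size: int = 5,
    max_size: int = 1500,
    fdr_threshold: float = 0.1,
    top: int = 30,
    test_depletion: bool = False,
) -> EnrichmentTable:
    """Hypergeometric enrichment of every module against every signature.

    Signature sizes are taken after intersection with the population;
    signatures outside [min_size, max_size] are excluded before testing.
    BH correction runs across all tested (module, signature, direction)
    combinations, then at most ``top`` signatures per module at
    FDR < ``fdr_threshold`` are reported, most significant first.
    Set ``fdr_threshold=1.0`` (and a large ``top``) for the unfiltered table.
    """
    assignment = partition.assignment if hasattr(partition, "assignment") else dict(partition)
    if not population:
        raise ValueError("empty population")
    modules: dict[str, set[str]] = {}
    for gene, module in assignment.items():
        modules.setdefault(module, set()).add(gene)
    for module, genes in modules.items():
        if not genes:
            raise ValueError(f"empty module {module}")
        stray = genes - population
        if stray:
            raise ValueError(f"module {module} genes outside population: {sorted(stray)[:5]}")
    N = len(population)
    sig_genes = {
        name: genes & population
        for name, genes in signatures.items()
    }
    sig_genes = {
        name: genes
        for name, genes in sig_genes.items()
        if min_size <= len(genes) <= max_size
    }

    rows = []
    for module in sorted(modules, key=_module_sort_key):
        genes = modules[module]
        n = len(genes)
        for name in sig_genes:
            K = len(sig_genes[name])
            k = len(genes & sig_genes[name])
            rows.append((module, name, k, n, K, N, hypergeom_upper_tail(k, n, K, N), "enriched"))
            if test_depletion:
                rows.append((module, name, k, n, K, N, hypergeom_lower_tail(k, n, K, N), "depleted"))

    table = pd.DataFrame(
        rows,
        columns=[
            "module", "signature", "overlap", "module_size",
            "signature_size", "population_size", "p_value", "direction",
        ],
    )
    table["fdr"] = bh_fdr(table["p_value"]) if len(table) else []
    if len(table):
        table["neg_log10_fdr"] = neg_log10(table["fdr"].to_numpy())
        table = table[table["fdr"] < fdr_threshold]
        table = (
            table.sort_values(["module", "p_value", "signature"], kind="stable")
            .groupby("module", sort=False)
            .head(top)
            .reset_index(drop=True)
        )
    else:
        table["neg_log10_fdr"] = []
    return EnrichmentTable(table=table)


def _module_sort_key(label: str):
    # numeric ordering for M1, M2, ... labels; fall back to plain string
    if label.startswith("M") and label[1:].isdigit():
        return (0, int(label[1:]), label)
    return (1, 0, label)
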