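"""Module and gene expression dynamics across the time course.

Summaries follow the display pipeline of the time-course heatmaps: median
expression across donors within each (condition, timepoint) group, then
either row z-scores (across group medians) or log2 fold changes against
each condition's baseline group, optionally averaged per module, with
hierarchical row ordering by 1 − Pearson distance and average linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .clustering import Partition
from .selection import GeneMatrix

__all__ = [
    "ModuleProfile",
    "group_medians",
    "zscore_rows",
    "fold_change_vs_baseline",
    "module_mean_profile",
    "hierarchical_order",
]

logger = logging.getLogger(__name__)


@dataclass
class ModuleProfile:
    """Gene (or module) × (condition, timepoint) summary matrix."""

    values: pd.DataFrame  # columns are (condition, timepoint) tuples
    mode: str  # "median-z" or "fold-change"
    baseline: dict[str, tuple[str, str]] | None = None
    constant_rows: list[str] | None = None


def group_medians(genes: GeneMatrix) -> pd.DataFrame:
    """Median across donors within each (condition, timepoint) group.

    Columns are ordered by condition then time_order; a single-donor group
    contributes its lone sample as the median.
    """
    meta = genes.samples
    cells = meta.drop_duplicates(subset=["condition", "timepoint"]).sort_values(
        ["condition", "time_order"], kind="stable"
    )
    columns, data = [], []
    for cond, tp in zip(cells["condition"], cells["timepoint"]):
        samples = meta.index[(meta["condition"] == cond) & (meta["timepoint"] == tp)]
        columns.append((cond, tp))
        data.append(np.median(genes.values[list(samples)].to_numpy(dtype=float), axis=1))
    out = pd.DataFrame(np.column_stack(data), index=genes.values.index)
    out.columns = pd.MultiIndex.from_tuples(columns, names=["condition", "timepoint"])
    return out


def zscore_rows(profile: pd.DataFrame) -> ModuleProfile:
    """Per-row z-scores (mean 0, sd 1 with n−1) across group columns.

    Constant rows cannot be standardized; they become all-zero and are
    listed in ``constant_rows``.
    """
    data = profile.to_numpy(dtype=float)
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    sd[sd == 0] = 1.0
    z = (data - mean) / sd
    z[constant] = 0.0
    flagged = list(profile.index[constant])
    if flagged:
        logger.warning("%d constant rows z-scored to zero", len(flagged))
    return ModuleProfile(
        values=pd.DataFrame(z, index=profile.index, columns=profile.columns),
        mode="median-z",
        constant_rows=flagged,
    )


def fold_change_vs_baseline(
    profile: pd.DataFrame, baseline: dict[str, str] | str
) -> ModuleProfile:
    """log2 fold change of each group column vs. its condition's baseline.

    ``baseline`` maps condition → baseline timepoint label (a single label
    applies to every condition).  Input is log2 expression, so the fold
    change is a simple column difference and the baseline column is 0.
    """
    conditions = profile.columns.get_level_values("condition").unique()
    if isinstance(baseline, str):
        baseline = {c: baseline for c in conditions}
    refs: dict[str, tuple[str, str]] = {}
    out = profile.copy().astype(float)
    for cond in conditions:
        if cond not in baseline:
            raise ValueError(f"no baseline timepoint for condition {cond}")
        key = (cond, baseline[cond])
        if key not in profile.columns:
            raise ValueError(f"baseline group {key} absent from profile")
        refs[cond] = key
        cols = [c for c in profile.columns if c[0] == cond]
        out.loc[:, cols] = profile.loc[:, cols].to_numpy() - profile.loc[:, [key]].to_numpy()
    return ModuleProfile(values=out, mode="fold-change", baseline=refs)


def module_mean_profile(profile: ModuleProfile, partition: Partition) -> pd.DataFrame:
    """Unweighted mean of member-gene rows per module, modules in label order."""
    rows = []
    labels = partition.labels()
    modules = partition.modules()
    for label in labels:
        members = sorted(modules[label])
        missing = [g for g in members if g not in profile.values.index]
        if missing:
            raise ValueError(f"module {label} genes absent from profile: {missing[:5]}")
        rows.append(profile.values.loc[members].mean(axis=0))
    return pd.DataFrame(rows, index=labels, columns=profile.values.columns)


def hierarchical_order(matrix: pd.DataFrame) -> list[int]:
    """Row ordering by agglomerative clustering with 1 − Pearson r distance
    and average linkage.

    Constant rows have undefined correlation; r is taken as 0 (distance 1).
    Deterministic: ties resolve by input row order (scipy's stable merge).
    """
    data = matrix.to_numpy(dtype=float)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 rows to order")
    sd = data.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant rows: correlation treated as 0", int(constant.sum()))
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(data)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return list(hierarchy.leaves_list(linkage))
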