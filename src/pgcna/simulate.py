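"""Synthetic multi-donor, multi-condition expression time courses.

The generator emulates the design of a bead-array differentiation time
course: several donors sampled per (condition, timepoint) cell, planted
co-expression modules that follow smooth per-condition trajectories,
several probes per gene, and Gaussian measurement noise.  Ground truth
(module membership, differential expression, signatures) ships with the
dataset so every pipeline stage can be scored without any download.

Draw order from the single seeded RNG is fixed and documented in the code:
trajectory coefficients, baselines, loadings, donor effects, probe counts,
probe offsets, gene noise, probe noise.  Regeneration from the same config
is therefore bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io import ExpressionMatrix, SignatureDatabase
from .overlap import DESet

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "simulate_timecourse",
    "planted_signatures",
    "simulate_de_benchmark",
    "adjusted_rand_index",
]

NULL_MODULE = "M0"


@dataclass
class SimConfig:
    """Generator settings; defaults are the package's standard benchmark.

    400 genes in 8 modules (10% of genes belong to no module), 2
    conditions × 8 timepoints × 3 donors, ~1.3 probes per gene, module
    trajectories are cubic polynomials in normalized time with standard
    normal coefficients, orthonormalized across modules (unit RMS over the
    condition × timepoint grid), gene loadings U(0.5, 1.5), donor effect
    sd 0.2, probe offset sd 0.3, per-sample noise sd 0.5.
    """

    n_genes: int = 400
    n_modules: int = 8
    probes_per_gene_mean: float = 1.3
    timepoints: list[str] = field(default_factory=lambda: [f"t{i}" for i in range(8)])
    conditions: list[str] = field(default_factory=lambda: ["C1", "C2"])
    n_donors: int = 3
    loading_range: tuple[float, float] = (0.5, 1.5)
    donor_sd: float = 0.2
    probe_offset_sd: float = 0.3
    probe_noise_sd: float = 0.1
    noise_sd: float = 0.5
    null_fraction: float = 0.1
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    de_truth_log2fc: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_modules, self.n_donors) < 1:
            raise ValueError("counts must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        if not 0 <= self.null_fraction < 1:
            raise ValueError("null fraction must lie in [0, 1)")
        n_module_genes = round(self.n_genes * (1 - self.null_fraction))
        if n_module_genes < 4 * self.n_modules:
            raise ValueError("module sizes would fall below 4 genes")


@dataclass
class SyntheticDataset:
    """A simulated time course bundled with its ground truth."""

    expression: ExpressionMatrix
    annotation: dict[str, str]
    true_partition: dict[str, str]  # gene -> M1..Mk, null genes M0
    true_de: list[DESet]
    signatures: SignatureDatabase
    noiseless: pd.DataFrame  # genes x (condition, timepoint), no noise terms
    config: SimConfig

    @property
    def module_genes(self) -> set[str]:
        return {g for g, m in self.true_partition.items() if m != NULL_MODULE}


def _module_trajectories(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """Smooth, mutually decorrelated module trajectories on the group grid.

    Each trajectory is a cubic polynomial per condition.  The centered
    span of such functions on the grid has dimension 4·n_conditions − 1;
    module trajectories are built inside that span from a random rotation
    (N(0,1) draws) of its orthonormal basis so that they are exactly
    uncorrelated across modules.  When the requested module count exceeds
    the span dimension by one, a regular-simplex frame is used instead —
    the maximally separated configuration, with constant pairwise
    correlation −1/(n_modules − 1).  Rows are scaled to unit variance
    across the condition × timepoint grid.
    """
    n_cond, n_tp = len(config.conditions), len(config.timepoints)
    n_groups = n_cond * n_tp
    u = np.linspace(0.0, 1.0, n_tp)
    basis = np.vstack([u**p for p in range(4)])  # 4 x n_timepoints
    span = np.zeros((4 * n_cond, n_groups))
    for c in range(n_cond):
        span[4 * c : 4 * c + 4, c * n_tp : (c + 1) * n_tp] = basis
    span -= span.mean(axis=1, keepdims=True)
    _, sv, vt = np.linalg.svd(span, full_matrices=False)
    rank = int(np.sum(sv > 1e-9 * sv[0]))
    m = config.n_modules
    if m > rank + 1:
        raise ValueError(
            f"at most {rank + 1} well-separated cubic trajectories exist "
            f"for {n_cond} conditions; reduce n_modules or add conditions"
        )
    rotation, _ = np.linalg.qr(rng.standard_normal((rank, rank)))
    onb = rotation @ vt[:rank]  # rank x n_groups, orthonormal centered rows
    if m <= rank:
        traj = onb[:m]
    else:
        # m = rank + 1: vertices of a regular simplex in the span
        frame = np.eye(m) - 1.0 / m
        proj = np.linalg.svd(frame)[0][:, :rank]
        frame = frame @ proj
        frame /= np.linalg.norm(frame, axis=1, keepdims=True)
        traj = frame @ onb
    sd = traj.std(axis=1)
    if np.any(sd < 1e-12):
        raise RuntimeError("degenerate (constant) module trajectory; use another seed")
    return traj / sd[:, None]


def simulate_timecourse(config: SimConfig | None = None, n_decoys: int = 20) -> SyntheticDataset:
    """Generate one synthetic dataset from ``config`` (bit-reproducible).

    A gene's latent value in sample (condition, timepoint, donor) is
    baseline + loading × trajectory(module, condition, timepoint)
    + donor effect + N(0, noise sd²); each of its probes adds a fixed
    probe offset and small probe noise.  Null genes have zero loading.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    n_cond, n_tp, n_don = len(config.conditions), len(config.timepoints), config.n_donors
    n_groups = n_cond * n_tp
    n_samples = n_groups * n_don

    traj = _module_trajectories(rng, config)  # draw 1
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)  # draw 2
    loading = rng.uniform(*config.loading_range, config.n_genes)  # draw 3
    donor_effect = rng.normal(0.0, config.donor_sd, (config.n_genes, n_cond, n_don))  # draw 4

    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    n_module_genes = round(config.n_genes * (1 - config.null_fraction))
    module_of = np.full(config.n_genes, -1)
    module_of[:n_module_genes] = np.arange(n_module_genes) % config.n_modules
    loading[module_of < 0] = 0.0

    group_cols = [(c, t) for c in config.conditions for t in config.timepoints]
    signal = np.zeros((config.n_genes, n_groups))
    planted = module_of >= 0
    signal[planted] = loading[planted, None] * traj[module_of[planted]]
    noiseless = baseline[:, None] + signal

    sample_ids, meta_rows = [], []
    latent = np.empty((config.n_genes, n_samples))
    col = 0
    for ci, cond in enumerate(config.conditions):
        for ti, tp in enumerate(config.timepoints):
            for di in range(n_don):
                sid = f"{cond}_{tp}_D{di + 1}"
                sample_ids.append(sid)
                meta_rows.append((sid, f"D{di + 1}", cond, tp, ti))
                latent[:, col] = noiseless[:, ci * n_tp + ti] + donor_effect[:, ci, di]
                col += 1
    latent += rng.normal(0.0, config.noise_sd, latent.shape)  # draw 5

    n_probes = 1 + rng.poisson(max(config.probes_per_gene_mean - 1.0, 0.0), config.n_genes)  # draw 6
    probe_ids, probe_gene_rows, annotation = [], [], {}
    for gi, gene in enumerate(genes):
        for j in range(n_probes[gi]):
            pid = f"P{gi + 1:04d}_{j + 1}"
            probe_ids.append(pid)
            probe_gene_rows.append(gi)
            annotation[pid] = gene
    probe_offsets = rng.normal(0.0, config.probe_offset_sd, len(probe_ids))  # draw 7
    probe_values = latent[probe_gene_rows] + probe_offsets[:, None]
    probe_values += rng.normal(0.0, config.probe_noise_sd, probe_values.shape)  # draw 8

    values = pd.DataFrame(probe_values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    samples = pd.DataFrame(
        meta_rows, columns=["sample_id", "donor", "condition", "timepoint", "time_order"]
    ).set_index("sample_id")
    expression = ExpressionMatrix(values=values, samples=samples)

    true_partition = {
        g: (NULL_MODULE if module_of[i] < 0 else f"M{module_of[i] + 1}") for i, g in enumerate(genes)
    }
    noiseless_df = pd.DataFrame(noiseless, index=genes)
    noiseless_df.columns = pd.MultiIndex.from_tuples(group_cols, names=["condition", "timepoint"])
    true_de = _true_de_sets(noiseless_df, config)

    dataset = SyntheticDataset(
        expression=expression,
        annotation=annotation,
        true_partition=true_partition,
        true_de=true_de,
        signatures=SignatureDatabase(sets={}),
        noiseless=noiseless_df,
        config=config,
    )
    dataset.signatures = planted_signatures(dataset, n_decoys=n_decoys)
    return dataset


def _true_de_sets(noiseless: pd.DataFrame, config: SimConfig) -> list[DESet]:
    """Gene sets whose noiseless profile shifts vs. the condition's first
    timepoint by more than the truth threshold (default 1 log2 unit)."""
    sets: list[DESet] = []
    for cond in config.conditions:
        base = noiseless[(cond, config.timepoints[0])]
        for tp in config.timepoints[1:]:
            delta = noiseless[(cond, tp)] - base
            for direction, mask in (
                ("induced", delta > config.de_truth_log2fc),
                ("repressed", delta < -config.de_truth_log2fc),
            ):
                sets.append(
                    DESet(
                        condition=cond,
                        timepoint=tp,
                        direction=direction,
                        genes=frozenset(noiseless.index[mask]),
                    )
                )
    return sets


def planted_signatures(dataset: SyntheticDataset, n_decoys: int = 20) -> SignatureDatabase:
    """One exact signature per planted module plus random decoy sets.

    Decoys are drawn (reproducibly, from seed+1) from the whole gene
    population with sizes U{10..50}.
    """
    rng = np.random.default_rng(dataset.config.seed + 1)
    genes = sorted(dataset.true_partition)
    sets: dict[str, frozenset[str]] = {}
    modules: dict[str, set[str]] = {}
    for gene, module in dataset.true_partition.items():
        if module != NULL_MODULE:
            modules.setdefault(module, set()).add(gene)
    for module in sorted(modules, key=lambda m: int(m[1:])):
        sets[f"SIG_{module}"] = frozenset(modules[module])
    for d in range(n_decoys):
        size = int(rng.integers(10, 51))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"DECOY_{d + 1:03d}"] = frozenset(members.tolist())
    collections = {name: ("planted" if name.startswith("SIG_") else "decoy") for name in sets}
    return SignatureDatabase(sets=sets, collections=collections)


def simulate_de_benchmark(
    n_null: int = 900,
    n_shifted: int = 100,
    shift: float = 2.0,
    n_per_group: int = 4,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, set[str]]:
    """Two-group benchmark for the differential-expression caller.

    ``n_shifted`` probes carry a planted mean shift (log2 units) between
    groups, the rest are null.  Returns the probe-level matrix (two
    conditions, one timepoint, ``n_per_group`` donors each) and the truth
    set of shifted probe ids.
    """
    rng = np.random.default_rng(seed)
    n = n_null + n_shifted
    base = rng.normal(8.0, 1.0, n)
    a = base[:, None] + rng.normal(0.0, noise_sd, (n, n_per_group))
    b = base[:, None] + rng.normal(0.0, noise_sd, (n, n_per_group))
    shifted = rng.choice(n, size=n_shifted, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_shifted)
    b[shifted] += (signs * shift)[:, None]
    probes = [f"P{i + 1:05d}" for i in range(n)]
    sample_ids = [f"A_t0_D{d + 1}" for d in range(n_per_group)] + [
        f"B_t0_D{d + 1}" for d in range(n_per_group)
    ]
    values = pd.DataFrame(
        np.hstack([a, b]), index=pd.Index(probes, name="probe_id"), columns=sample_ids
    )
    samples = pd.DataFrame(
        {
            "donor": [f"D{d + 1}" for d in range(n_per_group)] * 2,
            "condition": ["A"] * n_per_group + ["B"] * n_per_group,
            "timepoint": ["t0"] * 2 * n_per_group,
            "time_order": [0] * 2 * n_per_group,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = {probes[i] for i in shifted}
    return ExpressionMatrix(values=values, samples=samples), truth


def recover_modules(
    dataset: SyntheticDataset,
    n_runs: int = 100,
    keep: int = 10,
    base_seed: int = 42,
    selection_config=None,
):
    """Run the standard recovery pipeline on a synthetic dataset.

    Probe selection → probe merge → k=3 Spearman network → Louvain
    ensemble → max-modularity partition.  Returns (partition, gene matrix,
    correlation graph).
    """
    from .clustering import cluster_ensemble, select_partition
    from .network import build_network
    from .pipeline import _default_contrasts
    from .selection import (
        SelectionConfig,
        differential_probes,
        merge_probes_to_genes,
        select_informative,
        variance_filter,
    )

    config = selection_config or SelectionConfig()
    expr = dataset.expression
    contrasts = _default_contrasts(expr)
    de_results = [differential_probes(expr, c, config) for c in contrasts]
    selected = select_informative(de_results, variance_filter(expr, config))
    genes = merge_probes_to_genes(expr, selected, dataset.annotation)
    graph = build_network(genes, k=3)
    ensemble = cluster_ensemble(graph, n_runs=n_runs, keep=keep, base_seed=base_seed)
    return select_partition(ensemble), genes, graph


def score_recovery(dataset: SyntheticDataset, partition) -> dict:
    """ARI vs the planted partition and the top-signature match rate.

    ARI is computed over genes with a planted module (true label != M0:
    null genes have no module to recover).  A recovered module "matches"
    when its most significant planted signature is the signature of the
    planted module contributing most of its genes; modules dominated by
    null genes are skipped.
    """
    from .enrichment import enrich_modules

    assignment = partition.assignment if hasattr(partition, "assignment") else dict(partition)
    common = [
        g for g in assignment if dataset.true_partition.get(g, NULL_MODULE) != NULL_MODULE
    ]
    ari = adjusted_rand_index(
        {g: dataset.true_partition[g] for g in common},
        {g: assignment[g] for g in common},
    )
    population = set(assignment)
    table = enrich_modules(
        partition, dataset.signatures, population, fdr_threshold=1.0 + 1e-9, top=1
    ).table
    top_sig = dict(zip(table["module"], table["signature"]))
    matched = total = 0
    modules: dict[str, list[str]] = {}
    for gene, label in assignment.items():
        modules.setdefault(label, []).append(gene)
    for label, members in modules.items():
        truth_labels = [dataset.true_partition.get(g, NULL_MODULE) for g in members]
        dominant = max(set(truth_labels), key=truth_labels.count)
        if dominant == NULL_MODULE:
            continue
        total += 1
        matched += top_sig.get(label) == f"SIG_{dominant}"
    return {
        "ari": ari,
        "signature_match_rate": matched / total if total else float("nan"),
        "n_modules": len(modules),
    }


def de_power(dataset: SyntheticDataset, p_threshold: float = 0.05, fc_threshold: float = 1.5) -> dict:
    """Sensitivity and empirical null FDR of the BH-adjusted DE caller.

    For every timepoint, the two conditions are contrasted across donors.
    A (probe, timepoint) instance is a true positive when its gene's
    noiseless between-condition difference is >= 2 log2 units and the
    caller flags it in the right direction; a false discovery is a flagged
    instance whose gene is a null (M0, zero-difference) gene.
    """
    from .selection import SelectionConfig, differential_probes

    if len(dataset.config.conditions) != 2:
        raise ValueError("DE power scoring expects exactly 2 conditions")
    config = SelectionConfig(
        de_p_threshold=p_threshold, de_fc_threshold=fc_threshold, de_adjust=True
    )
    expr = dataset.expression
    c1, c2 = dataset.config.conditions
    called_true = total_true = called_null = total_called = 0
    for tp in dataset.config.timepoints:
        contrast = (expr.group_samples(c1, tp), expr.group_samples(c2, tp))
        up, down = differential_probes(expr, contrast, config)
        delta = dataset.noiseless[(c1, tp)] - dataset.noiseless[(c2, tp)]
        for probe in expr.probe_ids:
            gene = dataset.annotation[probe]
            d = float(delta[gene])
            flagged = probe in up or probe in down
            if abs(d) >= 2.0:
                total_true += 1
                called_true += (probe in up and d > 0) or (probe in down and d < 0)
            if flagged:
                total_called += 1
                called_null += dataset.true_partition[gene] == NULL_MODULE
    return {
        "sensitivity": called_true / total_true if total_true else float("nan"),
        "null_fdr": called_null / total_called if total_called else 0.0,
        "n_true": total_true,
        "n_called": total_called,
    }


def adjusted_rand_index(part_a, part_b) -> float:
    """Permutation-adjusted Rand index between two partitions.

    Accepts Partition objects or plain gene → label dicts; the two must
    cover the same gene universe.
    """
    a = part_a.assignment if hasattr(part_a, "assignment") else dict(part_a)
    b = part_b.assignment if hasattr(part_b, "assignment") else dict(part_b)
    if set(a) != set(b):
        raise ValueError("partitions cover different gene universes")
    genes = sorted(a)
    return float(adjusted_rand_score([a[g] for g in genes], [b[g] for g in genes]))
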