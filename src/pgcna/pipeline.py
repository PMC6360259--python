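"""End-to-end PGCNA orchestration from a single YAML config.

Stages run in order — probe selection, probe→gene merge, Spearman network,
Louvain ensemble, partition selection, signature enrichment, module
dynamics — writing every intermediate artifact plus a JSON manifest of
seeds, thresholds and per-stage counters.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from importlib.metadata import version as pkg_version
from pathlib import Path

import yaml

from . import clustering, dynamics, io, network, selection

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    expression: str
    metadata: str
    annotation: str
    out_dir: str
    gmt: str | None = None
    truth_partition: str | None = None
    selection: selection.SelectionConfig = field(default_factory=selection.SelectionConfig)
    contrasts: list[tuple[list[str], list[str]]] = field(default_factory=list)
    k: int = 3
    n_runs: int = clustering.DEFAULT_N_RUNS
    keep: int = clustering.DEFAULT_KEEP
    base_seed: int = clustering.DEFAULT_BASE_SEED
    strategy: str = "max_modularity"
    enrich_min_size: int = 5
    enrich_max_size: int = 1500
    enrich_fdr: float = 0.1
    enrich_top: int = 30
    baseline_timepoint: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        sel = selection.SelectionConfig(**raw.pop("selection", {}))
        cfg = cls(selection=sel, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for label, path in (
            ("expression", self.expression),
            ("metadata", self.metadata),
            ("annotation", self.annotation),
        ):
            if not Path(path).is_file():
                raise FileNotFoundError(f"{label} file not found: {path}")
        if self.strategy == "enrichment" and not self.gmt:
            raise ValueError("enrichment selection strategy requires a GMT file")
        if self.gmt and not Path(self.gmt).is_file():
            raise FileNotFoundError(f"GMT file not found: {self.gmt}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": _version(),
        "seeds": {"base_seed": config.base_seed},
        "thresholds": {
            "de_p": config.selection.de_p_threshold,
            "de_fc": config.selection.de_fc_threshold,
            "variance": config.selection.variance_threshold,
            "k": config.k,
            "n_runs": config.n_runs,
            "keep": config.keep,
            "enrich_fdr": config.enrich_fdr,
        },
        "counts": {},
        "outputs": {},
        "stages_completed": [],
    }
    try:
        _run_stages(config, out, manifest)
    except Exception as exc:  # noqa: BLE001 - manifest must record the failure
        manifest["error"] = {"stage": manifest.get("current_stage"), "cause": str(exc)}
        _write_manifest(manifest, out)
        raise RuntimeError(
            f"pipeline failed at stage {manifest.get('current_stage')}: {exc}"
        ) from exc
    _write_manifest(manifest, out)
    return manifest


def _run_stages(config: PipelineConfig, out: Path, manifest: dict) -> None:
    t0 = time.perf_counter()

    def stage_done(name: str) -> None:
        manifest["stages_completed"].append(name)
        logger.info("stage %s done (%.1fs elapsed)", name, time.perf_counter() - t0)

    manifest["current_stage"] = "select"
    expr = io.read_expression_tsv(config.expression, config.metadata)
    annotation = io.read_probe_annotation(config.annotation)
    contrasts = config.contrasts or config.selection.contrasts or _default_contrasts(expr)
    de_results = [
        selection.differential_probes(expr, contrast, config.selection) for contrast in contrasts
    ]
    de_probes = set().union(*(u | d for u, d in de_results)) if de_results else set()
    var_probes = selection.variance_filter(expr, config.selection)
    selected = selection.select_informative(de_results, var_probes)
    genes = selection.merge_probes_to_genes(expr, selected, annotation)
    genes_path = out / "genes.tsv"
    table = genes.values.copy()
    table.index.name = "gene"
    table.to_csv(genes_path, sep="\t", float_format="%.17g")
    manifest["counts"].update(
        {
            "probes_total": len(expr.probe_ids),
            "probes_de": len(de_probes),
            "probes_variance": len(var_probes),
            "probes_selected": len(selected),
            "genes_merged": len(genes.genes),
        }
    )
    manifest["outputs"]["genes"] = str(genes_path)
    stage_done("select")

    manifest["current_stage"] = "network"
    graph = network.build_network(genes, k=config.k)
    manifest["counts"].update(
        {
            "pairs_evaluated": graph.n_pairs_total,
            "edges_retained": graph.n_edges_retained,
        }
    )
    stage_done("network")

    manifest["current_stage"] = "cluster"
    ensemble = clustering.cluster_ensemble(
        graph, n_runs=config.n_runs, keep=config.keep, base_seed=config.base_seed
    )
    signatures = io.read_gmt(config.gmt) if config.gmt else None
    population = set(genes.genes)
    partition = clustering.select_partition(
        ensemble,
        strategy=config.strategy,
        signatures=signatures,
        population=population if signatures else None,
    )
    part_path = out / "partition.tsv"
    io.write_partition_tsv(partition.assignment, part_path)
    ens_path = out / "ensemble.tsv"
    with open(ens_path, "w", encoding="utf-8") as handle:
        handle.write("rank\tseed\tQ\tn_modules\n")
        for rank, part in enumerate(ensemble.partitions, 1):
            handle.write(f"{rank}\t{part.seed}\t{part.modularity:.12f}\t{len(part)}\n")
    net_path = out / "net.gexf"
    io.write_network_gexf(graph.graph, partition.assignment, net_path)
    manifest["counts"]["modules_found"] = len(partition)
    manifest["counts"]["best_modularity"] = partition.modularity
    manifest["outputs"].update(
        {"partition": str(part_path), "ensemble": str(ens_path), "network": str(net_path)}
    )
    stage_done("cluster")

    if signatures is not None:
        manifest["current_stage"] = "enrich"
        from . import enrichment as enr

        table = enr.enrich_modules(
            partition,
            signatures,
            population,
            min_size=config.enrich_min_size,
            max_size=config.enrich_max_size,
            fdr_threshold=config.enrich_fdr,
            top=config.enrich_top,
        )
        enrich_path = out / "enrichment.tsv"
        table.table.to_csv(enrich_path, sep="\t", index=False)
        manifest["outputs"]["enrichment"] = str(enrich_path)
        stage_done("enrich")

    manifest["current_stage"] = "dynamics"
    medians = dynamics.group_medians(genes)
    zprof = dynamics.zscore_rows(medians)
    prof_path = out / "profiles.tsv"
    flat = zprof.values.copy()
    flat.columns = [f"{c}|{t}" for c, t in flat.columns]
    flat.to_csv(prof_path, sep="\t", float_format="%.17g")
    module_prof = dynamics.module_mean_profile(zprof, partition)
    mod_path = out / "module_profiles.tsv"
    flat_m = module_prof.copy()
    flat_m.columns = [f"{c}|{t}" for c, t in flat_m.columns]
    flat_m.to_csv(mod_path, sep="\t", float_format="%.17g")
    manifest["outputs"].update({"profiles": str(prof_path), "module_profiles": str(mod_path)})
    stage_done("dynamics")

    if config.truth_partition:
        manifest["current_stage"] = "score"
        from .simulate import NULL_MODULE, adjusted_rand_index

        truth = io.read_partition_tsv(config.truth_partition)
        common = [g for g in partition.assignment if truth.get(g, NULL_MODULE) != NULL_MODULE]
        manifest["counts"]["ari_vs_truth"] = adjusted_rand_index(
            {g: truth[g] for g in common}, {g: partition.assignment[g] for g in common}
        )
        stage_done("score")
    manifest.pop("current_stage", None)


def _default_contrasts(expr) -> list[tuple[list[str], list[str]]]:
    """Every condition-pair at each timepoint, plus each timepoint vs. the
    condition's first timepoint — the selection design of a time course."""
    contrasts = []
    meta = expr.samples
    conditions = sorted(meta["condition"].unique())
    for cond in conditions:
        sub = meta[meta["condition"] == cond].sort_values("time_order", kind="stable")
        tps = list(dict.fromkeys(sub["timepoint"]))
        base = expr.group_samples(cond, tps[0])
        for tp in tps[1:]:
            contrasts.append((expr.group_samples(cond, tp), base))
    timepoints = sorted(meta["timepoint"].unique())
    for tp in timepoints:
        for i, c1 in enumerate(conditions):
            for c2 in conditions[i + 1 :]:
                a, b = expr.group_samples(c1, tp), expr.group_samples(c2, tp)
                if a and b:
                    contrasts.append((a, b))
    return contrasts


def _version() -> str:
    try:
        return pkg_version("pgcna")
    except Exception:  # pragma: no cover - not installed
        return "unknown"


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, default=str)
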