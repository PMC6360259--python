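"""Readers and writers for the on-disk artifacts of a PGCNA run.

Expression matrices are tab-delimited text with probes in rows and samples
in columns; per-sample design information (donor, condition, timepoint and
an explicit integer time ordering) lives in a separate metadata TSV, in the
style of GEO sample annotation tables.  Gene signatures use the GMT format
and networks are exchanged as GEXF (or GraphML) so they open directly in
Gephi-style viewers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SignatureDatabase",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_probe_annotation",
    "read_gmt",
    "write_gmt",
    "write_network_gexf",
    "write_network_graphml",
    "read_network",
    "read_partition_tsv",
    "write_partition_tsv",
]

METADATA_COLUMNS = ("donor", "condition", "timepoint", "time_order")


@dataclass
class ExpressionMatrix:
    """Probe-level log2 expression with per-sample design metadata.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, indexed by probe id with one column
        per sample id.  Values are assumed already normalized and
        log2-transformed; no transformation is applied here.
    samples
        DataFrame indexed by sample id with columns ``donor``,
        ``condition``, ``timepoint`` and ``time_order`` (integer rank of
        the timepoint within its condition).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        missing_cols = [c for c in METADATA_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise ValueError(f"sample metadata missing columns: {missing_cols}")
        orphans = [s for s in self.values.columns if s not in self.samples.index]
        if orphans:
            raise ValueError(f"samples without metadata: {orphans}")
        vals = self.values.to_numpy()
        if vals.size and not np.all(np.isfinite(vals.astype(float))):
            raise ValueError("expression matrix contains non-finite values")
        # keep metadata aligned to, and ordered like, the expression columns
        self.samples = self.samples.loc[list(self.values.columns)]

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def groups(self) -> list[tuple[str, str]]:
        """(condition, timepoint) cells in condition-then-time_order order."""
        meta = self.samples.drop_duplicates(subset=["condition", "timepoint"])
        meta = meta.sort_values(["condition", "time_order"], kind="stable")
        return list(zip(meta["condition"], meta["timepoint"]))

    def group_samples(self, condition: str, timepoint: str) -> list[str]:
        mask = (self.samples["condition"] == condition) & (
            self.samples["timepoint"].astype(str) == str(timepoint)
        )
        return list(self.samples.index[mask])


@dataclass
class SignatureDatabase:
    """Named gene sets, e.g. a merged compendium of curated signatures."""

    sets: dict[str, frozenset[str]]
    collections: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [name for name, genes in self.sets.items() if not genes]
        if empty:
            raise ValueError(f"empty signatures: {empty}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_expression_tsv(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a probes × samples TSV plus its sample metadata TSV.

    The expression file's first column must be named ``probe_id``; every
    remaining column is a sample and must appear in the metadata file.
    """
    values = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if values.index.name != "probe_id":
        raise ValueError(
            f"first column of {path} must be 'probe_id', got {values.index.name!r}"
        )
    non_numeric = [c for c in values.columns if not np.issubdtype(values[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric expression columns: {non_numeric}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError("metadata file must have a 'sample_id' column")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id rows in metadata")
    meta = meta.set_index("sample_id")
    meta["time_order"] = meta["time_order"].astype(int)
    return ExpressionMatrix(values=values, samples=meta)


def write_expression_tsv(
    matrix: ExpressionMatrix, path: str | Path, metadata_path: str | Path
) -> None:
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.17g")
    meta = matrix.samples.copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t")


def read_probe_annotation(path: str | Path) -> dict[str, str]:
    """Read a two-column probe_id → gene symbol TSV (header required).

    Probes mapping to no gene may simply be absent, or carry an empty
    symbol; empty symbols are dropped so the probe counts as unmapped.
    """
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if table.shape[1] < 2:
        raise ValueError("annotation file needs probe_id and gene columns")
    probes, genes = table.iloc[:, 0], table.iloc[:, 1]
    if probes.duplicated().any():
        dups = probes[probes.duplicated()].tolist()
        raise ValueError(f"duplicate probe ids in annotation: {dups}")
    return {p: g for p, g in zip(probes, genes) if g}


def read_gmt(path: str | Path) -> SignatureDatabase:
    """Read a GMT file: name, description, then member genes, tab-separated."""
    sets: dict[str, frozenset[str]] = {}
    collections: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, description = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"duplicate signature name: {name}")
            genes = frozenset(g for g in fields[2:] if g)
            sets[name] = genes
            collections[name] = description
    return SignatureDatabase(sets=sets, collections=collections)


def write_gmt(db: SignatureDatabase, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, genes in db.items():
            desc = db.collections.get(name, "na") or "na"
            handle.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def _attach_partition(graph: nx.Graph, partition: dict[str, str] | None) -> nx.Graph:
    out = graph.copy()
    if partition is not None:
        missing = [n for n in out.nodes if n not in partition]
        if missing:
            raise ValueError(f"partition missing nodes: {missing[:10]}")
        nx.set_node_attributes(out, {n: partition[n] for n in out.nodes}, "module")
    return out


def write_network_gexf(
    graph: nx.Graph, partition: dict[str, str] | None, path: str | Path
) -> None:
    """Write a weighted co-expression graph as GEXF.

    Node attribute ``module`` carries the partition label; edge weights are
    the correlation values.  Round-trips through :func:`read_network`.
    """
    nx.write_gexf(_attach_partition(graph, partition), path)


def write_network_graphml(
    graph: nx.Graph, partition: dict[str, str] | None, path: str | Path
) -> None:
    nx.write_graphml(_attach_partition(graph, partition), path)


def read_network(path: str | Path) -> nx.Graph:
    path = Path(path)
    if path.suffix == ".graphml":
        graph = nx.read_graphml(path)
    else:
        graph = nx.read_gexf(path)
    return nx.Graph(graph)


def read_partition_tsv(path: str | Path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))


def write_partition_tsv(assignment: dict[str, str], path: str | Path) -> None:
    table = pd.DataFrame(
        {"gene": list(assignment), "module": [assignment[g] for g in assignment]}
    )
    table.to_csv(path, sep="\t", index=False)
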