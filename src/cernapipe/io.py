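"""Readers and writers for every external format the pipeline touches.

All tabular artifacts are plain TSV.  Writers may prepend a single
``#``-prefixed provenance line (config hash + seed); readers skip such
lines.  Networks are exchanged as SIF (human-readable) and GraphML
(lossless: node classes, edge weights, miRNA evidence).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ExpressionDataset,
    FormatError,
    GeneSetCollection,
    InteractionDB,
    RNAClass,
    classes_from_mapping,
)
from .network import CeRNANetwork

log = logging.getLogger(__name__)


def _write_tsv(df: pd.DataFrame, path: Path | str, provenance: str | None, index: bool) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=index)


# ---------------------------------------------------------------------------
# expression matrices and the gene -> class map
# ---------------------------------------------------------------------------

def read_class_map(path: Path | str) -> dict[str, RNAClass]:
    """Two-column TSV ``gene<TAB>class`` -> mapping."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["gene", "rna_class"],
                     dtype=str)
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise FormatError(f"duplicate genes in class map: {dupes}")
    try:
        return {g: RNAClass(c) for g, c in zip(df["gene"], df["rna_class"])}
    except ValueError as exc:
        raise FormatError(f"unknown RNA class in {path}: {exc}") from exc


def write_class_map(classes: Mapping[str, RNAClass] | pd.Series, path: Path | str) -> None:
    items = classes.items() if isinstance(classes, dict) else classes.items()
    df = pd.DataFrame([(g, str(RNAClass(c))) for g, c in items])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, header=False)


def read_expression(
    path: Path | str,
    class_map: Mapping[str, RNAClass],
    subtype: str,
    strict: bool = True,
) -> ExpressionDataset:
    """Read a genes x samples TSV (first column gene ids, header sample ids).

    Genes absent from *class_map* raise in strict mode and are dropped
    with a warning otherwise; readers never silently drop rows.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene rows: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample columns: {dupes}")
    bad = df.map(lambda v: not isinstance(v, (int, float, np.integer, np.floating)))
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValueError(f"{path}: non-numeric cell at gene {df.index[g]!r}, "
                         f"sample {df.columns[s]!r}")
    unmapped = [g for g in df.index if g not in class_map]
    if unmapped:
        if strict:
            raise ValueError(f"{path}: genes missing from class map: {unmapped[:10]}")
        log.warning("%s: dropping %d genes missing from class map", path, len(unmapped))
        df = df.drop(index=unmapped)
    classes = classes_from_mapping(df.index, class_map)
    return ExpressionDataset(subtype=subtype, values=df.astype(float), classes=classes)


def write_expression(dataset: ExpressionDataset, path: Path | str,
                     provenance: str | None = None) -> None:
    df = dataset.values.copy()
    df.index.name = "gene"
    _write_tsv(df, path, provenance, index=True)


# ---------------------------------------------------------------------------
# interactions, clinical, GMT
# ---------------------------------------------------------------------------

def read_interactions(path: Path | str) -> InteractionDB:
    """TSV ``mirna<TAB>target[<TAB>source]``; duplicates collapsed."""
    rows: list[tuple[str, str]] = []
    sources: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 columns")
            mirna, target = parts[0], parts[1]
            if mirna == target:
                raise ValueError(f"{path}:{lineno}: self-pair {mirna!r}")
            rows.append((mirna, target))
            if len(parts) > 2:
                sources.add(parts[2])
    if not rows:
        log.warning("%s: empty interaction file", path)
    return InteractionDB(pairs=set(rows), source=";".join(sorted(sources)) or "unspecified")


def write_interactions(db: InteractionDB, path: Path | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for mirna, target in sorted(db.pairs):
            fh.write(f"{mirna}\t{target}\t{db.source}\n")


def read_clinical(path: Path | str) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"sample": str, "subtype": str})
    return ClinicalTable(records=df)


def write_clinical(table: ClinicalTable, path: Path | str,
                   provenance: str | None = None) -> None:
    _write_tsv(table.records, path, provenance, index=False)


def read_gmt(path: Path | str) -> GeneSetCollection:
    """Standard GMT: ``name<TAB>description<TAB>gene...`` per line."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description "
                                  "and >= 1 gene")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, genes)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: Path | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# networks: SIF and GraphML
# ---------------------------------------------------------------------------

def write_network(network: CeRNANetwork, path: Path | str, fmt: str = "graphml") -> None:
    """Export a network as ``sif`` or ``graphml``.

    SIF rows are ``nodeA<TAB>cerna<TAB>nodeB``; isolated nodes appear as
    single-token lines (standard SIF convention).  GraphML keeps node
    classes, edge weights, evidence and supporting miRNAs.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "sif":
        with open(path, "w") as fh:
            covered: set[str] = set()
            for a, b in sorted(network.edge_set()):
                fh.write(f"{a}\tcerna\t{b}\n")
                covered.update((a, b))
            for n in sorted(network.node_set() - covered):
                fh.write(f"{n}\n")
    elif fmt == "graphml":
        g = nx.Graph(tag=network.tag, **{k: v for k, v in network.graph.graph.items()
                                         if k != "tag"})
        for n in sorted(network.graph.nodes):
            g.add_node(n, rna_class=str(network.node_class(n)))
        for a, b in sorted(network.edge_set()):
            d = network.graph.edges[a, b]
            g.add_edge(a, b, weight=repr(float(d["weight"])), evidence=d["evidence"],
                       supporting_mirnas=",".join(d["supporting_mirnas"]))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: Path | str) -> CeRNANetwork:
    """Read back a GraphML export written by :func:`write_network`."""
    g = nx.read_graphml(path)
    net = CeRNANetwork(tag=g.graph.get("tag", "unknown"))
    net.graph.graph.update({k: v for k, v in g.graph.items() if k != "tag"})
    for n, d in g.nodes(data=True):
        net.add_node(n, RNAClass(d["rna_class"]))
    for a, b, d in g.edges(data=True):
        net.graph.add_edge(
            a, b,
            weight=float(d["weight"]),
            supporting_mirnas=tuple(d["supporting_mirnas"].split(",")),
            evidence=d["evidence"],
        )
    return net


def write_edge_table(network: CeRNANetwork, path: Path | str,
                     provenance: str | None = None) -> None:
    cols = ["node_a", "node_b", "class_a", "class_b", "weight", "evidence",
            "supporting_mirnas"]
    df = pd.DataFrame(network.edge_records(), columns=cols)
    _write_tsv(df, path, provenance, index=False)
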