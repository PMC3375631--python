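"""Readers and writers for the plain-text interchange formats.

Supported formats: Broad-style GMT gene-set files, two-column tab-separated
edge lists with ``#`` comments, TSV expression matrices with a header row of
sample ids, two-column sample→label files, RNK pre-ranked lists, per-gene
DE-profile TSVs, and the package's own result tables.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    ExpressionDataset,
    GeneSet,
    ParseError,
    PathwayCollection,
    PathwayGraph,
    RankedList,
    ValidationError,
    validate_result_table,
)

logger = logging.getLogger(__name__)

GRAPH_SUFFIXES = (".tsv", ".txt", ".edges")


def read_gmt(path: str | os.PathLike) -> PathwayCollection:
    """Read a GMT file: one gene set per line as
    ``set_id<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are collapsed; duplicate set ids raise.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields (id, description, genes), got {len(fields)}"
                )
            set_id, name, *genes = fields
            members = frozenset(g for g in genes if g)
            if not members:
                raise ParseError(f"{path}: line {lineno}: no member genes")
            sets.append(GeneSet(set_id, name, members))
    return PathwayCollection(tuple(sets))


def write_gmt(collection: PathwayCollection, path: str | os.PathLike) -> None:
    """Write a collection to GMT; members are sorted for determinism."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.members)]) + "\n")


def read_edge_list(
    path: str | os.PathLike,
    pathway_id: str,
    nodes_path: str | os.PathLike | None = None,
) -> PathwayGraph:
    """Read an undirected edge list (two tab-separated gene ids per line).

    ``#``-prefixed and blank lines are skipped. Reversed or repeated edges
    collapse to one; self-loops are dropped with a warning but their node is
    kept. ``nodes_path``, if given, lists one gene per line and lets
    isolated pathway genes enter the graph.
    """
    edges: list[tuple[str, str]] = []
    extra: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected exactly 2 tab-separated "
                    f"gene ids, got {len(fields)}"
                )
            a, b = fields
            if a == b:
                logger.warning(
                    "%s: line %d: dropping self-loop on %r", path, lineno, a
                )
                extra.add(a)
                continue
            edges.append((a, b))
    if nodes_path is not None:
        with open(nodes_path, encoding="utf-8") as fh:
            for line in fh:
                g = line.strip()
                if g and not g.startswith("#"):
                    extra.add(g)
    return PathwayGraph.from_edges(pathway_id, edges, extra_nodes=extra)


def write_edge_list(graph: PathwayGraph, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(graph.edges):
            fh.write(f"{a}\t{b}\n")
        isolated = graph.nodes - {g for e in graph.edges for g in e}
        for g in sorted(isolated):
            fh.write(f"# isolated node: {g}\n")


def read_graph_dir(dirpath: str | os.PathLike) -> list[PathwayGraph]:
    """Read every edge-list file in a directory; the file stem is the
    pathway id. Graphs are returned sorted by pathway id."""
    dirpath = Path(dirpath)
    graphs = []
    for p in sorted(dirpath.iterdir()):
        if p.suffix in GRAPH_SUFFIXES and p.is_file():
            graphs.append(read_edge_list(p, pathway_id=p.stem))
    if not graphs:
        raise ValidationError(f"no edge-list files found in {dirpath}")
    return graphs


def read_expression(
    matrix_path: str | os.PathLike, labels_path: str | os.PathLike
) -> ExpressionDataset:
    """Read an expression matrix TSV (gene rows, sample-id header) and a
    two-column sample→label TSV; label order is aligned by sample id."""
    try:
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        values = values.astype(float)
    except ValueError as exc:
        raise ParseError(f"{matrix_path}: non-numeric expression value: {exc}")
    labels_df = pd.read_csv(
        labels_path,
        sep="\t",
        header=None,
        names=["sample", "label"],
        dtype=str,
        comment="#",
    )
    labels = pd.Series(
        labels_df["label"].values, index=labels_df["sample"].values
    )
    missing = set(values.columns) - set(labels.index)
    if missing:
        raise ValidationError(
            f"samples in matrix missing from labels: {sorted(missing)}"
        )
    return ExpressionDataset(values, labels.loc[list(values.columns)])


def write_expression(
    dataset: ExpressionDataset,
    matrix_path: str | os.PathLike,
    labels_path: str | os.PathLike,
) -> None:
    dataset.values.to_csv(matrix_path, sep="\t", float_format="%.6f")
    with open(labels_path, "w", encoding="utf-8") as fh:
        for sample, label in dataset.labels.items():
            fh.write(f"{sample}\t{label}\n")


def read_rnk(path: str | os.PathLike) -> RankedList:
    """Read a RNK file (gene_id<TAB>statistic) into a RankedList; input
    need not be sorted."""
    genes: list[str] = []
    stats: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected gene_id<TAB>statistic"
                )
            try:
                stat = float(fields[1])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric statistic "
                    f"{fields[1]!r}"
                )
            genes.append(fields[0])
            stats.append(stat)
    return RankedList.from_unsorted(genes, stats)


def write_rnk(ranked: RankedList, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g, s in zip(ranked.genes, ranked.stats):
            fh.write(f"{g}\t{s:.10g}\n")


def read_de_profile(path: str | os.PathLike) -> dict[str, float]:
    """Read a per-gene DE-intensity TSV (gene_id<TAB>value in [0,1])."""
    profile: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected gene_id<TAB>value"
                )
            try:
                v = float(fields[1])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric value")
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"{path}: line {lineno}: DE value {v} outside [0,1]"
                )
            profile[fields[0]] = v
    return profile


def write_de_profile(
    profile: Mapping[str, float], path: str | os.PathLike
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(profile):
            fh.write(f"{g}\t{profile[g]:.6f}\n")


_FLOAT_FMT = "{:.10f}"


def _fmt(v: object) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "NA"
    if isinstance(v, (float, np.floating)):
        return _FLOAT_FMT.format(v)
    return str(v)


def write_results(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a result table to TSV with fixed decimal formatting.

    Columns beyond the canonical five (pathway_id, score, p_value, q_value,
    rank) are appended after them. Rows are written in rank order when ranks
    are present, else in input order.
    """
    validate_result_table(table)
    table = table.copy()
    canonical = [
        c for c in ("pathway_id", "score", "p_value", "q_value", "rank")
        if c in table.columns
    ]
    extra = [c for c in table.columns if c not in canonical]
    cols = canonical + extra
    if "rank" in table.columns and table["rank"].notna().all() and len(table):
        table = table.sort_values("rank")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for _, row in table.iterrows():
            out = []
            for c in cols:
                v = row[c]
                if c == "rank" and v is not None and not pd.isna(v):
                    out.append(str(int(v)))
                else:
                    out.append(_fmt(v))
            fh.write("\t".join(out) + "\n")


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    """Read a result table written by :func:`write_results`."""
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "rank" in table.columns and table["rank"].notna().all():
        table["rank"] = table["rank"].astype(int)
    return validate_result_table(table)


def read_base_results(path: str | os.PathLike) -> pd.DataFrame:
    """Read an external base-method table; requires at least pathway_id and
    p_value columns (any extra columns are preserved)."""
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "p_value" not in table.columns:
        raise ValidationError(
            f"{path}: base result table needs a p_value column; "
            f"found {list(table.columns)}"
        )
    return validate_result_table(table)


def read_scores(path: str | os.PathLike) -> dict[str, float]:
    """Read per-pathway scores from a TSV with pathway_id and score columns
    (a result table works), or a headerless two-column file."""
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "pathway_id" in table.columns and "score" in table.columns:
        return dict(zip(table["pathway_id"], table["score"].astype(float)))
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected pathway_id and score columns")
    return dict(zip(raw[0].astype(str), raw[1].astype(float)))
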