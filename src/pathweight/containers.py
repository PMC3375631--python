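"""Core in-memory containers shared across the package.

Gene identifiers are opaque, case-sensitive strings throughout: no
symbol/Entrez mapping is attempted, and two identifiers are the same gene
iff they are equal strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input violates a documented invariant."""


class ParseError(ValueError):
    """A file is syntactically malformed."""


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (the 'document' of the IDF analogy)."""

    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.set_id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PathwayCollection:
    """An ordered collection of gene sets with a derived gene universe."""

    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate set_id(s) in collection: {dupes}")

    @property
    def universe(self) -> frozenset[str]:
        u: set[str] = set()
        for s in self.sets:
            u |= s.members
        return frozenset(u)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.set_id for s in self.sets)

    def get(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)


def _canonical_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PathwayGraph:
    """Undirected gene-interaction graph of one pathway.

    Nodes are genes, edges are interactions; self-loops are disallowed and
    each unordered pair appears at most once.
    """

    pathway_id: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValidationError(
                    f"graph {self.pathway_id!r}: self-loop on {a!r}"
                )
            if (a, b) != _canonical_edge(a, b):
                raise ValidationError(
                    f"graph {self.pathway_id!r}: edge {(a, b)!r} not canonical"
                )
            if a not in self.nodes or b not in self.nodes:
                raise ValidationError(
                    f"graph {self.pathway_id!r}: edge {(a, b)!r} has endpoint "
                    "outside the node set"
                )

    @classmethod
    def from_edges(
        cls,
        pathway_id: str,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
    ) -> "PathwayGraph":
        """Build a graph, canonicalising edge orientation and collapsing
        duplicates; self-loops must be filtered by the caller."""
        canon = frozenset(_canonical_edge(a, b) for a, b in edges)
        nodes = set(extra_nodes)
        for a, b in canon:
            nodes.add(a)
            nodes.add(b)
        return cls(pathway_id, frozenset(nodes), canon)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with a two-class phenotype.

    `values` is a DataFrame indexed by gene id with sample ids as columns;
    `labels` maps each sample id to one of exactly two class labels.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = sorted(self.values.index[self.values.index.duplicated()])
            raise ValidationError(f"duplicate gene id(s): {dupes[:5]}")
        if list(self.values.columns) != list(self.labels.index):
            missing = set(self.values.columns) - set(self.labels.index)
            if missing:
                raise ValidationError(
                    f"samples missing from labels: {sorted(missing)}"
                )
            # align label order to matrix column order by sample id
            self.labels = self.labels.loc[self.values.columns]
        classes = sorted(self.labels.unique())
        if len(classes) != 2:
            raise ValidationError(
                f"expected exactly 2 phenotype classes, got {classes}"
            )
        counts = self.labels.value_counts()
        if counts.min() < 2:
            raise ValidationError(
                "each phenotype class needs >= 2 samples for a standard "
                f"deviation; got {counts.to_dict()}"
            )
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise ParseError("expression matrix contains non-numeric values")

    @property
    def classes(self) -> tuple[str, str]:
        a, b = sorted(self.labels.unique())
        return (a, b)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


class RankedList:
    """Genes ordered by a differential-expression statistic, descending.

    Ties in the statistic are broken by gene id ascending so the order is
    deterministic.
    """

    __slots__ = ("genes", "stats", "_pos")

    def __init__(self, genes: Iterable[str], stats: Iterable[float]):
        genes = tuple(genes)
        stats = np.asarray(list(stats), dtype=float)
        if len(genes) != len(stats):
            raise ValidationError("genes and statistics differ in length")
        if len(set(genes)) != len(genes):
            raise ValidationError("ranked list contains duplicate gene ids")
        if np.any(np.diff(stats) > 0):
            raise ValidationError("statistics must be non-increasing")
        self.genes = genes
        self.stats = stats
        self._pos = {g: i for i, g in enumerate(genes)}

    @classmethod
    def from_unsorted(
        cls, genes: Iterable[str], stats: Iterable[float]
    ) -> "RankedList":
        genes = list(genes)
        stats = np.asarray(list(stats), dtype=float)
        order = np.lexsort((genes, -stats))
        return cls([genes[i] for i in order], stats[order])

    def index(self, gene: str) -> int:
        """0-based position of a gene in the list."""
        return self._pos[gene]

    def positions(self, gene_ids: Iterable[str]) -> np.ndarray:
        """0-based positions of the given genes, in ascending position order;
        genes absent from the list are dropped."""
        pos = sorted(self._pos[g] for g in gene_ids if g in self._pos)
        return np.asarray(pos, dtype=np.intp)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._pos


@dataclass(frozen=True)
class EnrichmentScore:
    """A running-sum enrichment score and where its extreme occurs.

    `peak_index` is 1-based in the ranked list.
    """

    es: float
    peak_index: int


RESULT_COLUMNS = ("pathway_id", "score", "p_value", "q_value", "rank")


def validate_result_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-pathway result table (pathway_id unique; p/q in [0,1];
    ranks, when present, a permutation of 1..n)."""
    if "pathway_id" not in table.columns:
        raise ValidationError("result table lacks a pathway_id column")
    if table["pathway_id"].duplicated().any():
        dupes = sorted(table.loc[table["pathway_id"].duplicated(), "pathway_id"])
        raise ValidationError(f"duplicate pathway_id(s): {dupes}")
    for col in ("p_value", "q_value"):
        if col in table.columns:
            vals = table[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValidationError(f"{col} outside [0,1]")
    if "rank" in table.columns and table["rank"].notna().all() and len(table):
        ranks = sorted(int(r) for r in table["rank"])
        if ranks != list(range(1, len(table) + 1)):
            raise ValidationError("ranks are not a permutation of 1..n")
    return table
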