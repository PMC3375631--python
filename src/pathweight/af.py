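"""Appearance-frequency (IDF) weighting of gene sets.

Treating each pathway as a document and its genes as terms, a gene's
appearance frequency is the number of pathways in the collection that
contain it. The inverse-document-frequency weight idf(g) = ln(N / n_g),
with N the pathway count and n_g the appearance frequency, downweights
ubiquitous housekeeping-like genes (idf = 0 exactly when a gene sits in
every pathway) and upweights pathway-specific ones. Term frequency is
fixed at 1: a gene almost never occurs more than once in a single pathway
map, so a TF component carries no information here.

The log base only rescales all weights by a constant, which the
running-sum normalisation cancels, so the natural log is used throughout
and the choice cannot affect enrichment scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    ExpressionDataset,
    GeneSet,
    PathwayCollection,
    RankedList,
    EnrichmentScore,
    ValidationError,
)
from . import enrichment


@dataclass(frozen=True)
class AppearanceCounts:
    """Per-gene pathway-membership counts over a collection of N pathways."""

    counts: Mapping[str, int]
    n_pathways: int

    def __post_init__(self) -> None:
        for g, c in self.counts.items():
            if not 1 <= c <= self.n_pathways:
                raise ValidationError(
                    f"count for {g!r} is {c}, outside 1..{self.n_pathways}"
                )


def appearance_counts(collection: PathwayCollection) -> AppearanceCounts:
    """Count, for every gene in the universe, the number of distinct sets
    containing it. Σ counts equals Σ set sizes exactly."""
    if len(collection) == 0:
        raise ValidationError("cannot count appearances in an empty collection")
    counts: dict[str, int] = {}
    for s in collection:
        for g in s.members:
            counts[g] = counts.get(g, 0) + 1
    return AppearanceCounts(counts, len(collection))


def idf_weights(counts: AppearanceCounts) -> dict[str, float]:
    """idf(g) = ln(N / count_g); zero iff the gene is in every pathway,
    strictly decreasing in the appearance count."""
    n = counts.n_pathways
    return {g: float(np.log(n / c)) for g, c in counts.counts.items()}


def frequency_histogram(
    counts: AppearanceCounts,
) -> dict[int, tuple[int, float]]:
    """Histogram of appearance counts: bin -> (n_genes, proportion of the
    universe). Proportions sum to 1."""
    total = len(counts.counts)
    bins: dict[int, int] = {}
    for c in counts.counts.values():
        bins[c] = bins.get(c, 0) + 1
    return {c: (k, k / total) for c, k in sorted(bins.items())}


def histogram_frame(counts: AppearanceCounts) -> pd.DataFrame:
    hist = frequency_histogram(counts)
    return pd.DataFrame(
        {
            "appearance_count": list(hist),
            "n_genes": [v[0] for v in hist.values()],
            "proportion": [v[1] for v in hist.values()],
        }
    )


def idf_frame(counts: AppearanceCounts) -> pd.DataFrame:
    """TSV-ready table of gene, appearance count and idf weight."""
    idf = idf_weights(counts)
    genes = sorted(counts.counts)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "count": [counts.counts[g] for g in genes],
            "idf": [idf[g] for g in genes],
        }
    )


def af_weighted_es(
    ranked: RankedList,
    gene_set: GeneSet,
    idf: Mapping[str, float],
    convention: str = "extreme",
) -> EnrichmentScore:
    """Running-sum ES with IDF hit weights.

    Members with idf = 0 (ubiquitous genes) contribute no hit increment but
    are still hits, so they never count as misses and the miss normalisation
    is unchanged relative to the equal-weight statistic.
    """
    present = [g for g in gene_set.members if g in ranked]
    for g in present:
        if g not in idf:
            raise ValidationError(f"gene {g!r} has no IDF weight")
    if present and all(idf[g] == 0 for g in present):
        raise ValidationError(
            f"set {gene_set.set_id}: contains only ubiquitous genes "
            "(all IDF weights zero)"
        )
    return enrichment.running_sum_es(
        ranked, gene_set, weights=idf, convention=convention
    )


def run_af_analysis(
    dataset: ExpressionDataset,
    collection: PathwayCollection,
    n_perm: int = 1000,
    seed: int = 0,
    idf_collection: PathwayCollection | None = None,
    convention: str = "extreme",
    scheme: str = "auto",
) -> pd.DataFrame:
    """Per-pathway AF-weighted enrichment over a collection.

    IDF weights come from ``idf_collection`` when given (a reference
    collection keeps weights stable under filtering), else from the scored
    collection itself. Weights are applied identically in the permutation
    null. Returns a result table with ES, permutation p, BH q and ranks.
    """
    source = idf_collection if idf_collection is not None else collection
    idf = idf_weights(appearance_counts(source))
    if len(set(idf.values())) == 1:
        # constant IDF (e.g. a single-pathway collection, where every idf
        # is 0) provably reduces to the equal-weight statistic
        idf = None
    return enrichment.enrichment_table(
        dataset,
        collection,
        n_perm=n_perm,
        seed=seed,
        weights=idf,
        convention=convention,
        scheme=scheme,
    )
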