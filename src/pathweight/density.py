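"""Topology-aware density scoring of pathway graphs.

A pathway whose differentially expressed (DE) genes form a tight cluster on
the interaction graph is treated as more informative than one whose DE
genes are scattered. For each gene g with DE intensity x(g) in [0, 1]:

    ds(g) = x(g) * sum_{g' != g} x(g') * penalty(d(g, g'))

where d is the unweighted shortest-path length and the penalty is
``decay**d`` (exponential, default) or ``1/d`` (inverse). Unreachable pairs
contribute nothing. The pathway score is the arithmetic mean of ds over ALL
graph nodes, so both the fraction of DE genes and their mutual proximity
raise the score. Pathways are ranked by descending score.

All-pairs shortest paths are computed with Floyd–Warshall (Θ(n³), exact for
the unit-weight graphs used here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import (
    PathwayGraph,
    RankedList,
    ValidationError,
)
from .enrichment import rank_table

logger = logging.getLogger(__name__)

#: sentinel for unreachable node pairs in a DistanceMatrix
UNREACHABLE = np.inf


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest-path lengths over a fixed node order.

    ``d`` is square, symmetric, zero on the diagonal, with
    :data:`UNREACHABLE` (inf) for disconnected pairs.
    """

    order: tuple[str, ...]
    d: np.ndarray

    def distance(self, a: str, b: str) -> float:
        i, j = self.order.index(a), self.order.index(b)
        return float(self.d[i, j])


@dataclass(frozen=True)
class DensityResult:
    pathway_id: str
    ds_pathway: float
    per_gene: Mapping[str, float]


def all_pairs_shortest_paths(graph: PathwayGraph) -> DistanceMatrix:
    """Floyd–Warshall over the pathway graph with unit edge weights."""
    if graph.n_nodes == 0:
        raise ValidationError(f"graph {graph.pathway_id!r} is empty")
    order = tuple(sorted(graph.nodes))
    idx = {g: i for i, g in enumerate(order)}
    n = len(order)
    d = np.full((n, n), UNREACHABLE)
    np.fill_diagonal(d, 0.0)
    for a, b in graph.edges:
        d[idx[a], idx[b]] = 1.0
        d[idx[b], idx[a]] = 1.0
    for k in range(n):
        np.minimum(d, d[:, k, None] + d[None, k, :], out=d)
    return DistanceMatrix(order, d)


def _penalty_matrix(d: np.ndarray, decay: float, penalty: str) -> np.ndarray:
    if not 0.0 < decay < 1.0:
        raise ValidationError(f"decay must lie in (0, 1); got {decay}")
    if penalty == "exp":
        p = np.power(decay, d)  # decay**inf == 0.0: unreachable drops out
    elif penalty == "inverse":
        with np.errstate(divide="ignore"):
            p = 1.0 / d  # 1/inf == 0.0
    else:
        raise ValidationError(
            f"unknown penalty {penalty!r}; use 'exp' or 'inverse'"
        )
    np.fill_diagonal(p, 0.0)  # g' != g: a gene never reinforces itself
    return p


def _profile_vector(
    order: tuple[str, ...], profile: Mapping[str, float], pathway_id: str
) -> np.ndarray:
    missing = [g for g in order if g not in profile]
    if missing:
        logger.info(
            "pathway %s: %d node(s) missing from the DE profile default to 0",
            pathway_id, len(missing),
        )
    x = np.array([float(profile.get(g, 0.0)) for g in order])
    if np.any((x < 0) | (x > 1)):
        raise ValidationError("DE intensities must lie in [0, 1]")
    return x


def gene_density_score(
    gene: str,
    distances: DistanceMatrix,
    profile: Mapping[str, float],
    decay: float = 0.5,
    penalty: str = "exp",
) -> float:
    """Density score of one gene: its own DE intensity times the
    distance-penalised DE intensities of every other reachable gene."""
    if gene not in distances.order:
        raise ValidationError(f"gene {gene!r} not in the distance matrix")
    p = _penalty_matrix(distances.d, decay, penalty)
    x = _profile_vector(distances.order, profile, pathway_id="<adhoc>")
    i = distances.order.index(gene)
    return float(x[i] * (p[i] @ x))


def pathway_density_score(
    graph: PathwayGraph,
    profile: Mapping[str, float],
    decay: float = 0.5,
    penalty: str = "exp",
) -> DensityResult:
    """Mean per-gene density score over all graph nodes (isolated and
    non-DE nodes contribute 0 but stay in the denominator)."""
    dm = all_pairs_shortest_paths(graph)
    p = _penalty_matrix(dm.d, decay, penalty)
    x = _profile_vector(dm.order, profile, graph.pathway_id)
    per_gene_arr = x * (p @ x)
    per_gene = dict(zip(dm.order, per_gene_arr.tolist()))
    return DensityResult(
        pathway_id=graph.pathway_id,
        ds_pathway=float(per_gene_arr.mean()),
        per_gene=per_gene,
    )


def de_profile_from_ranked(
    ranked: RankedList, quantile: float = 0.1, mode: str = "binary"
) -> dict[str, float]:
    """DE intensities from a ranked list.

    ``binary``: 1 for genes whose |statistic| falls in the top ``quantile``
    of the list (two-sided), else 0. ``continuous``: |statistic| scaled to
    [0, 1] by its maximum.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValidationError(f"quantile must lie in (0, 1]; got {quantile}")
    abs_stats = np.abs(ranked.stats)
    if mode == "binary":
        k = max(1, int(round(quantile * len(ranked))))
        # threshold at the k-th largest |stat|; ties all included
        thresh = np.sort(abs_stats)[::-1][k - 1]
        return {
            g: 1.0 if a >= thresh and a > 0 else 0.0
            for g, a in zip(ranked.genes, abs_stats)
        }
    if mode == "continuous":
        top = abs_stats.max()
        if top == 0:
            return {g: 0.0 for g in ranked.genes}
        return dict(zip(ranked.genes, (abs_stats / top).tolist()))
    raise ValidationError(
        f"unknown DE profile mode {mode!r}; use 'binary' or 'continuous'"
    )


def run_ds_analysis(
    graphs: Iterable[PathwayGraph],
    profile: Mapping[str, float],
    decay: float = 0.5,
    penalty: str = "exp",
) -> tuple[pd.DataFrame, dict[str, DensityResult]]:
    """Score a collection of pathway graphs against one DE profile.

    Returns (result table ranked by descending density score, ties broken
    by pathway id; per-pathway DensityResult map). A pathway with no genes
    in the profile scores 0 with a warning rather than erroring.
    """
    graphs = list(graphs)
    if not graphs:
        raise ValidationError("no pathway graphs supplied")
    ids = [g.pathway_id for g in graphs]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate pathway ids among the graphs")
    results: dict[str, DensityResult] = {}
    for g in graphs:
        if not (g.nodes & set(profile)):
            logger.warning(
                "pathway %s: no genes found in the DE profile; score is 0",
                g.pathway_id,
            )
        results[g.pathway_id] = pathway_density_score(
            g, profile, decay=decay, penalty=penalty
        )
    table = pd.DataFrame(
        {
            "pathway_id": [g.pathway_id for g in graphs],
            "score": [results[g.pathway_id].ds_pathway for g in graphs],
        }
    )
    return rank_table(table, key="score_desc"), results
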