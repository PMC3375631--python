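"""GSEA-style enrichment: signal-to-noise ranking, running-sum enrichment
scores with pluggable per-gene weights, permutation p-values, and BH FDR.

The enrichment score (ES) is the extreme of a running sum that walks the
ranked gene list, rising by a (normalised) weight at every set member and
falling by 1/(N - N_h) at every non-member — a weighted two-sample
Kolmogorov–Smirnov-type statistic. With equal weights this is the classic
unweighted GSEA statistic; supplying per-gene weights (e.g. IDF weights)
yields the appearance-frequency variant.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import (
    EnrichmentScore,
    ExpressionDataset,
    GeneSet,
    PathwayCollection,
    RankedList,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: below this per-class sample size, phenotype permutation is too coarse and
#: the batch runners fall back to gene-set permutation
MIN_CLASS_FOR_PHENOTYPE_PERM = 7

_SD_FLOOR_FACTOR = 0.2  # denominator floor, as a fraction of |class mean|

#: running-sum values this close to the extreme count as tied; the earliest
#: tied position is reported
PEAK_TIE_TOL = 1e-12


def _class_stats(
    values: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    sub = values[:, mask]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    # floor the sd at 0.2*|mean| (0.2 absolute for all-zero genes) so
    # constant genes never divide by zero
    floor = _SD_FLOOR_FACTOR * np.abs(mean)
    floor[floor == 0.0] = _SD_FLOOR_FACTOR
    return mean, np.maximum(sd, floor)


def signal_to_noise_values(
    dataset: ExpressionDataset, positive_class: str | None = None
) -> np.ndarray:
    """Per-gene signal-to-noise statistics in the dataset's gene order:
    (mean_1 - mean_2) / (sd_1 + sd_2), class 1 being `positive_class`
    (default: the lexicographically smaller label)."""
    c1, c2 = dataset.classes
    if positive_class is not None:
        if positive_class not in (c1, c2):
            raise ValidationError(
                f"positive_class {positive_class!r} is not one of {c1, c2}"
            )
        if positive_class == c2:
            c1, c2 = c2, c1
    labels = dataset.labels.to_numpy()
    values = dataset.values.to_numpy(dtype=float)
    m1, s1 = _class_stats(values, labels == c1)
    m2, s2 = _class_stats(values, labels == c2)
    return (m1 - m2) / (s1 + s2)


def signal_to_noise(
    dataset: ExpressionDataset, positive_class: str | None = None
) -> RankedList:
    """Rank genes by the two-class signal-to-noise ratio, descending; ties
    broken by gene id ascending."""
    stats = signal_to_noise_values(dataset, positive_class)
    return RankedList.from_unsorted(dataset.gene_ids, stats)


def _es_from_positions(
    hit_pos: np.ndarray,
    hit_weights: np.ndarray,
    n: int,
    convention: str,
) -> EnrichmentScore:
    """ES from 0-based hit positions and their (unnormalised) weights."""
    w_total = hit_weights.sum()
    if w_total <= 0:
        raise ValidationError(
            "set contains only zero-weight (ubiquitous) genes"
        )
    # rescale by the max weight: mathematically a no-op (the running sum is
    # scale-invariant) but it makes constant weights reduce to the
    # equal-weight statistic bit-exactly
    hit_weights = hit_weights / hit_weights.max()
    w_total = hit_weights.sum()
    n_hits = len(hit_pos)
    if n_hits == 0:
        raise ValidationError("set not represented in ranked list")
    if n_hits >= n:
        raise ValidationError(
            "set covers the entire ranked list; no misses to normalise"
        )
    step = np.full(n, -1.0 / (n - n_hits))
    step[hit_pos] = hit_weights / w_total
    running = np.cumsum(step)
    if convention == "extreme":
        values = np.abs(running)
    elif convention == "max":
        values = running
    else:
        raise ValidationError(
            f"unknown es convention {convention!r}; use 'extreme' or 'max'"
        )
    # earliest peak wins; exact ties (e.g. a symmetric negative and positive
    # extreme) are resolved to a tolerance so float noise cannot flip them
    peak = int(np.argmax(values >= values.max() - PEAK_TIE_TOL))
    return EnrichmentScore(es=float(running[peak]), peak_index=peak + 1)


def running_sum_es(
    ranked: RankedList,
    gene_set: GeneSet | Iterable[str],
    weights: Mapping[str, float] | None = None,
    convention: str = "extreme",
) -> EnrichmentScore:
    """Running-sum enrichment score of a gene set on a ranked list.

    The set is first restricted to genes present in the list. At a member
    ("hit") the sum rises by w(g)/W where W sums the member weights (equal
    weights when ``weights`` is None); at a non-member ("miss") it falls by
    1/(N - N_h). ES is the signed extreme of the running sum
    (``convention='extreme'``) or its maximum (``'max'``); the first peak
    wins ties. |ES| <= 1 always.
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else set(gene_set)
    present = [g for g in members if g in ranked]
    if not present:
        raise ValidationError("set not represented in ranked list")
    if weights is None:
        pos = ranked.positions(present)
        w = np.ones(len(pos))
    else:
        for g in present:
            if g not in weights:
                raise ValidationError(f"no weight provided for gene {g!r}")
            if weights[g] < 0:
                raise ValidationError(f"negative weight for gene {g!r}")
        pairs = sorted((ranked.index(g), float(weights[g])) for g in present)
        pos = np.array([p for p, _ in pairs], dtype=np.intp)
        w = np.array([wv for _, wv in pairs])
    return _es_from_positions(pos, w, len(ranked), convention)


def _permute_labels(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return rng.permutation(labels)


def _set_index_arrays(
    collection: PathwayCollection,
    gene_index: Mapping[str, int],
    weights: Mapping[str, float] | None,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-set arrays of dataset gene indices and per-gene weights, with
    genes absent from the dataset dropped (logged)."""
    idx_arrays: list[np.ndarray] = []
    w_arrays: list[np.ndarray] = []
    for s in collection:
        present = sorted(g for g in s.members if g in gene_index)
        dropped = len(s.members) - len(present)
        if dropped:
            logger.info(
                "set %s: dropping %d gene(s) absent from the expression "
                "matrix", s.set_id, dropped,
            )
        idx_arrays.append(
            np.array([gene_index[g] for g in present], dtype=np.intp)
        )
        if weights is None:
            w_arrays.append(np.ones(len(present)))
        else:
            w_arrays.append(
                np.array([float(weights.get(g, 0.0)) for g in present])
            )
    return idx_arrays, w_arrays


def _es_batch(
    stats: np.ndarray,
    gene_names: Sequence[str],
    idx_arrays: Sequence[np.ndarray],
    w_arrays: Sequence[np.ndarray],
    convention: str,
) -> np.ndarray:
    """ES of every set against the ranking induced by ``stats``."""
    order = np.lexsort((np.asarray(gene_names), -stats))
    rank_pos = np.empty(len(order), dtype=np.intp)
    rank_pos[order] = np.arange(len(order), dtype=np.intp)
    n = len(order)
    out = np.empty(len(idx_arrays))
    for i, (idx, w) in enumerate(zip(idx_arrays, w_arrays)):
        pos = rank_pos[idx]
        sorter = np.argsort(pos)
        out[i] = _es_from_positions(pos[sorter], w[sorter], n, convention).es
    return out


def pvalues_from_null(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Two-sided permutation p-values with the add-one correction:
    p = (#{|null| >= |obs|} + 1) / (B + 1), so p is never 0."""
    obs = np.abs(np.asarray(observed, dtype=float))
    null_abs = np.abs(np.asarray(null, dtype=float))
    b = (null_abs >= obs[:, None] if null_abs.ndim == 2 else
         null_abs[None, :] >= obs[:, None]).sum(axis=1)
    n_perm = null_abs.shape[-1]
    return (b + 1.0) / (n_perm + 1.0)


def permutation_pvalue(
    dataset: ExpressionDataset,
    gene_set: GeneSet,
    weights: Mapping[str, float] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    convention: str = "extreme",
    scheme: str = "phenotype",
) -> float:
    """Permutation p-value of one gene set's |ES| (see
    :func:`enrichment_table` for the batch variant sharing one null)."""
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    table = enrichment_table(
        dataset,
        PathwayCollection((gene_set,)),
        n_perm=n_perm,
        seed=seed,
        weights=weights,
        convention=convention,
        scheme=scheme,
    )
    return float(table["p_value"].iloc[0])


def enrichment_table(
    dataset: ExpressionDataset,
    collection: PathwayCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weights: Mapping[str, float] | None = None,
    convention: str = "extreme",
    scheme: str = "auto",
    positive_class: str | None = None,
) -> pd.DataFrame:
    """Score every set of a collection: ES, permutation p (one shared null
    per scheme), BH q, and ranks by p ascending.

    ``scheme`` is ``phenotype`` (permute sample labels and re-rank),
    ``gene_set`` (draw random sets of matched size from the ranked list —
    the fallback for tiny sample sizes), or ``auto``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if scheme == "auto":
        min_class = dataset.labels.value_counts().min()
        scheme = (
            "phenotype" if min_class >= MIN_CLASS_FOR_PHENOTYPE_PERM
            else "gene_set"
        )
    rng = np.random.default_rng(seed)
    gene_names = list(dataset.gene_ids)
    gene_index = {g: i for i, g in enumerate(gene_names)}
    idx_arrays, w_arrays = _set_index_arrays(collection, gene_index, weights)
    for s, idx, w in zip(collection, idx_arrays, w_arrays):
        if len(idx) == 0:
            raise ValidationError(
                f"set {s.set_id}: no members in the expression matrix"
            )
        if w.sum() <= 0:
            raise ValidationError(
                f"set {s.set_id}: contains only ubiquitous (zero-weight) genes"
            )

    obs_stats = signal_to_noise_values(dataset, positive_class)
    observed = _es_batch(obs_stats, gene_names, idx_arrays, w_arrays, convention)

    n_sets = len(collection)
    null = np.empty((n_sets, n_perm))
    if scheme == "phenotype":
        labels = dataset.labels.to_numpy()
        values = dataset.values.to_numpy(dtype=float)
        c1, c2 = dataset.classes
        if positive_class == c2:
            c1, c2 = c2, c1
        for b in range(n_perm):
            perm = _permute_labels(labels, rng)
            m1, s1 = _class_stats(values, perm == c1)
            m2, s2 = _class_stats(values, perm == c2)
            stats = (m1 - m2) / (s1 + s2)
            null[:, b] = _es_batch(
                stats, gene_names, idx_arrays, w_arrays, convention
            )
    elif scheme == "gene_set":
        n = len(gene_names)
        order = np.lexsort((np.asarray(gene_names), -obs_stats))
        rank_pos = np.empty(n, dtype=np.intp)
        rank_pos[order] = np.arange(n, dtype=np.intp)
        all_idx = np.arange(n, dtype=np.intp)
        for i, (idx, w) in enumerate(zip(idx_arrays, w_arrays)):
            k = len(idx)
            for b in range(n_perm):
                rand_idx = rng.choice(all_idx, size=k, replace=False)
                pos = np.sort(rank_pos[rand_idx])
                null[i, b] = _es_from_positions(pos, w, n, convention).es
    else:
        raise ValidationError(
            f"unknown permutation scheme {scheme!r}; "
            "use 'phenotype', 'gene_set' or 'auto'"
        )

    p = pvalues_from_null(observed, null)
    # per-set standardisation of ES against its own permutation null; a
    # significance-scaled score suitable as a p-value-weight source
    null_sd = null.std(axis=1, ddof=1)
    null_sd[null_sd == 0] = 1.0
    z = (observed - null.mean(axis=1)) / null_sd
    table = pd.DataFrame(
        {
            "pathway_id": list(collection.ids),
            "score": observed,
            "z_score": z,
            "p_value": p,
            "q_value": bh_fdr(p),
        }
    )
    return rank_table(table, key="p_asc")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, aligned to input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_table(results: pd.DataFrame, key: str = "p_asc") -> pd.DataFrame:
    """Assign ranks 1..n (1 = most significant) by ``score_desc`` or
    ``p_asc``; ties broken by pathway_id ascending."""
    col, ascending = {
        "score_desc": ("score", False),
        "p_asc": ("p_value", True),
    }.get(key, (None, None))
    if col is None:
        raise ValidationError(f"unknown ranking key {key!r}")
    if col not in results.columns or results[col].isna().any():
        raise ValidationError(f"ranking key column {col!r} missing or has NAs")
    out = results.copy()
    order = out.sort_values(
        [col, "pathway_id"], ascending=[ascending, True], kind="mergesort"
    ).index
    ranks = pd.Series(np.arange(1, len(out) + 1), index=order)
    out["rank"] = ranks.reindex(out.index).astype(int)
    return out
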