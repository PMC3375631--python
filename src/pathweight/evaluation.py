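"""Simulation-based evaluation of the package's statistical guarantees.

Each function here runs a self-contained experiment on synthetic data and
returns summary numbers: exact agreement of the fast enrichment-score path
with a brute-force reference, exact agreement of Floyd–Warshall with
breadth-first-search distances, calibration of permutation p-values under
the null, FDR control of the weighted-BH adjustment, separation of
clustered versus random DE placements by the density score, and recovery /
reproducibility gains of the weighted adjustments on paired datasets with
planted signal.

The brute-force references are deliberately independent code paths (plain
Python walks, networkx traversals) and are never used by the package's own
computations.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import GeneSet, PathwayCollection, PathwayGraph, RankedList
from . import adjust, af, density, enrichment, fixtures


# ---------------------------------------------------------------------------
# brute-force references


def brute_force_running_sum(
    genes: list[str],
    members: set[str],
    weights: Mapping[str, float] | None,
    convention: str = "extreme",
) -> tuple[float, int, list[float]]:
    """Reference running-sum walk in plain Python.

    Materialises the full running-sum vector and scans it for the signed
    extreme (or maximum), first peak winning ties. Returns
    (es, peak_index_1based, running_sum).
    """
    present = [g for g in genes if g in members]
    n, n_h = len(genes), len(present)
    if weights is None:
        w_of = lambda g: 1.0
    else:
        # same max-rescaling convention as the fast path (a mathematical
        # no-op; makes constant weights reduce to equal weights exactly)
        w_max = max(float(weights[g]) for g in present)
        w_of = lambda g: float(weights[g]) / w_max
    w_total = sum(w_of(g) for g in present)
    running: list[float] = []
    total = 0.0
    for g in genes:
        if g in members:
            total += w_of(g) / w_total
        else:
            total -= 1.0 / (n - n_h)
        running.append(total)
    values = [abs(v) for v in running] if convention == "extreme" else running
    top = max(values)
    best_i = next(
        i for i, v in enumerate(values)
        if v >= top - enrichment.PEAK_TIE_TOL
    )
    return running[best_i], best_i + 1, running


def es_oracle_agreement(
    n_instances: int = 1000,
    seed: int = 0,
    max_len: int = 20,
    max_set: int = 8,
) -> float:
    """Fraction of random instances (equal and random positive weights,
    both sign conventions) where the fast ES path matches the brute-force
    walk exactly, including the peak index."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(2, max_len + 1))
        genes = [f"g{i}" for i in range(n)]
        stats = np.sort(rng.standard_normal(n))[::-1]
        ranked = RankedList(genes, stats)
        k = int(rng.integers(1, min(max_set, n - 1) + 1))
        members = set(
            genes[i] for i in rng.choice(n, size=k, replace=False)
        )
        weights = None
        if rng.random() < 0.5:
            weights = {g: float(rng.uniform(0.1, 3.0)) for g in genes}
        convention = "extreme" if rng.random() < 0.5 else "max"
        got = enrichment.running_sum_es(
            ranked, members, weights=weights, convention=convention
        )
        want_es, want_peak, _ = brute_force_running_sum(
            genes, members, weights, convention
        )
        if got.peak_index == want_peak and np.isclose(
            got.es, want_es, rtol=0, atol=1e-12
        ):
            agree += 1
    return agree / n_instances


def apsp_oracle_agreement(
    n_graphs: int = 200, seed: int = 0, max_nodes: int = 50
) -> float:
    """Fraction of random graphs where Floyd–Warshall distances equal
    per-source BFS (networkx) distances exactly, unreachable included."""
    rng = np.random.default_rng(seed)
    agree = 0
    for gi in range(n_graphs):
        n = int(rng.integers(2, max_nodes + 1))
        p = float(rng.uniform(0.02, 0.3))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        names = {u: f"g{u:03d}" for u in g.nodes}
        graph = fixtures.PathwayGraph.from_edges(
            f"G{gi}",
            [(names[a], names[b]) for a, b in g.edges],
            extra_nodes=names.values(),
        )
        dm = density.all_pairs_shortest_paths(graph)
        ok = True
        for i, src in enumerate(dm.order):
            lengths = nx.single_source_shortest_path_length(
                g, int(src[1:])
            )
            for j, dst in enumerate(dm.order):
                want = lengths.get(int(dst[1:]), density.UNREACHABLE)
                if dm.d[i, j] != want:
                    ok = False
        agree += ok
    return agree / n_graphs


# ---------------------------------------------------------------------------
# null calibration


def null_pvalue_uniformity(
    n_sets: int = 500,
    n_genes: int = 1000,
    n_samples_per_class: int = 8,
    set_size: int = 20,
    n_perm: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation p-values of random gene sets on expression with no class
    difference, tested against U[0,1] with a Kolmogorov–Smirnov test."""
    spec = fixtures.FixtureSpec(
        seed=seed,
        n_genes=n_genes,
        n_samples_per_class=n_samples_per_class,
        n_pathways=1,
        set_size_range=(1, n_genes),
        sharing_profile={1: 1.0},
        effect_size=0.0,
    )
    # one flat "collection" only to reuse the expression generator
    base = fixtures.generate_collection(
        replace(spec, n_pathways=1, set_size_range=(n_genes, n_genes))
    )
    dataset = fixtures.generate_expression(spec, base, ())
    rng = np.random.default_rng(seed + 1)
    genes = list(dataset.gene_ids)
    sets = []
    for i in range(n_sets):
        idx = rng.choice(n_genes, size=set_size, replace=False)
        sets.append(
            GeneSet(f"S{i:04d}", "null set", frozenset(genes[j] for j in idx))
        )
    table = enrichment.enrichment_table(
        dataset,
        PathwayCollection(tuple(sets)),
        n_perm=n_perm,
        seed=seed + 2,
        scheme="phenotype",
    )
    ks = sps.kstest(table["p_value"].to_numpy(), "uniform")
    return {
        "ks_stat": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "mean_p": float(table["p_value"].mean()),
    }


def weighted_bh_fdr_simulation(
    n_reps: int = 500,
    n_pathways: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Empirical FDR of BH at ``alpha`` on weight-adjusted p-values under a
    full null: p ~ U[0,1], weights built from scores independent of p.

    Returns the mean false-discovery proportion and its Monte-Carlo
    standard error (all discoveries are false under the full null).
    """
    rng = np.random.default_rng(seed)
    fdp = np.empty(n_reps)
    ids = [f"P{i:04d}" for i in range(n_pathways)]
    for r in range(n_reps):
        p = rng.uniform(size=n_pathways)
        scores = dict(zip(ids, rng.standard_normal(n_pathways)))
        w = adjust.scores_to_weights(scores)
        w_arr = np.array([w[i] for i in ids])
        adjusted = np.minimum(1.0, p / w_arr)
        q = enrichment.bh_fdr(adjusted)
        n_disc = int((q <= alpha).sum())
        fdp[r] = 1.0 if n_disc > 0 else 0.0  # every discovery is false
    mean_fdp = float(fdp.mean())
    mc_se = float(fdp.std(ddof=1) / np.sqrt(n_reps))
    return {"empirical_fdr": mean_fdp, "mc_se": mc_se}


# ---------------------------------------------------------------------------
# density-score separation (clustered vs random/dispersed placements)


def clustered_vs_random_ds(
    n_graphs: int = 200,
    seed: int = 0,
    n_nodes: int = 30,
    n_de: int = 6,
    decay: float = 0.5,
    baseline: str = "random",
) -> float:
    """Fraction of random connected graphs on which a clustered DE
    placement scores strictly higher than a ``baseline`` (random or
    dispersed) placement of the same size."""
    wins = 0
    for i in range(n_graphs):
        spec = fixtures.FixtureSpec(
            seed=seed + i,
            graph_model="erdos_renyi",
            graph_param=0.15,
            graph_n_nodes=n_nodes,
            n_de=n_de,
            de_placement="clustered",
        )
        graph, prof_c = fixtures.generate_graph_with_de(spec, "P")
        _, prof_b = fixtures.generate_graph_with_de(
            replace(spec, de_placement=baseline), "P"
        )
        ds_c = density.pathway_density_score(graph, prof_c, decay=decay)
        ds_b = density.pathway_density_score(graph, prof_b, decay=decay)
        wins += ds_c.ds_pathway > ds_b.ds_pathway
    return wins / n_graphs


# ---------------------------------------------------------------------------
# paired-cohort recovery experiment (desk-scale analogue of a two-cohort
# reproducibility comparison)


def _recovery_collection(rng: np.random.Generator) -> tuple[
    PathwayCollection, list[str], set[str]
]:
    """40 sets over 700 pathway-specific + 15 ubiquitous genes.

    6 planted sets (15 specific members, 10 of which carry the shared
    signal, plus 4 ubiquitous), 8 housekeeping decoys (17 specific + 13
    ubiquitous: their enrichment rides on ubiquitous drift), 26 background
    sets (15 specific + 4 ubiquitous). Ubiquitous genes sit in over a
    third of all sets, so their IDF is small. Decoy and background ids
    sort before 'planted' so p-value ties never favour the planted sets.
    Returns (collection, planted ids, shared planted DE genes).
    """
    specific = [f"s{i:04d}" for i in range(700)]
    ubiquitous = [f"u{i:02d}" for i in range(15)]
    pool = rng.permutation(len(specific))
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = [specific[j] for j in pool[cursor: cursor + k]]
        cursor += k
        return out

    sets = []
    planted_ids: list[str] = []
    planted_de: set[str] = set()
    for i in range(6):
        sid = f"planted{i + 1}"
        planted_ids.append(sid)
        mine = take(15)
        planted_de.update(mine[j] for j in rng.choice(15, 10, replace=False))
        ubiq = list(rng.choice(ubiquitous, 4, replace=False))
        sets.append(GeneSet(sid, "planted", frozenset(mine + ubiq)))
    for i in range(8):
        ubiq = list(rng.choice(ubiquitous, 13, replace=False))
        sets.append(
            GeneSet(f"hk{i + 1}", "housekeeping decoy",
                    frozenset(take(17) + ubiq))
        )
    for i in range(26):
        ubiq = list(rng.choice(ubiquitous, 4, replace=False))
        sets.append(
            GeneSet(f"bg{i + 1:02d}", "background",
                    frozenset(take(15) + ubiq))
        )
    return PathwayCollection(tuple(sets)), planted_ids, planted_de


def _recovery_dataset(
    rng: np.random.Generator,
    collection: PathwayCollection,
    planted_de: set[str],
    n_drift: int,
    n_per: int = 8,
    effect: float = 1.2,
    drift_range: tuple[float, float] = (2.5, 4.0),
) -> fixtures.ExpressionDataset:
    """One cohort. Planted DE genes get the shared +effect class shift;
    ``n_drift`` of the ubiquitous genes get a cohort-specific upward shift
    (housekeeping/batch drift). Which genes drift, and how strongly, is
    uncorrelated between cohorts, so decoy enrichment does not replicate;
    pairing a severe with a mild cohort emulates two studies of unequal
    batch quality."""
    genes = sorted(collection.universe)
    samples = [f"s{i:03d}" for i in range(1, 2 * n_per + 1)]
    labels = pd.Series(["case"] * n_per + ["ctrl"] * n_per, index=samples)
    values = rng.standard_normal((len(genes), 2 * n_per))
    idx = {g: i for i, g in enumerate(genes)}
    for g in sorted(planted_de):
        values[idx[g], :n_per] += effect
    ubiq = [g for g in genes if g.startswith("u")]
    for g in sorted(rng.choice(ubiq, n_drift, replace=False)):
        values[idx[g], :n_per] += rng.uniform(*drift_range)
    frame = pd.DataFrame(values, index=genes, columns=samples)
    frame.index.name = "gene_id"
    return fixtures.ExpressionDataset(frame, labels)


def _recovery_graphs(
    rng: np.random.Generator,
    collection: PathwayCollection,
    planted_de: set[str],
    edge_p: float = 0.08,
) -> dict[str, PathwayGraph]:
    """One sparse graph per set, fixed for the whole replicate (pathway
    topology is a database object shared by cohorts). On planted graphs
    the shared DE members occupy one breadth-first neighbourhood; on decoy
    and background graphs the ubiquitous members are laid out by greedy
    farthest-point dispersal."""
    graphs: dict[str, PathwayGraph] = {}
    for s in collection:
        mem = sorted(s.members)
        n = len(mem)
        g = nx.gnp_random_graph(n, edge_p, seed=int(rng.integers(2**31)))
        if not nx.is_connected(g):
            comps = [sorted(c) for c in nx.connected_components(g)]
            for a, b in zip(comps, comps[1:]):
                g.add_edge(a[0], b[0])
        if s.set_id.startswith("planted"):
            special = [i for i, m in enumerate(mem) if m in planted_de]
            clustered = True
        else:
            special = [i for i, m in enumerate(mem) if m.startswith("u")]
            clustered = False
        order = list(range(n))
        if 0 < len(special) < n:
            if clustered:
                target = fixtures._clustered_nodes(g, len(special), 0, rng)
            else:
                target = fixtures._dispersed_nodes(g, len(special), rng)
            rest = [u for u in range(n) if u not in set(target)]
            others = [i for i in range(n) if i not in special]
            order = [0] * n
            for u, i in zip(target, special):
                order[u] = i
            for u, i in zip(rest, others):
                order[u] = i
        graphs[s.set_id] = PathwayGraph.from_edges(
            s.set_id,
            [(mem[order[a]], mem[order[b]]) for a, b in g.edges],
            extra_nodes=mem,
        )
    return graphs


def paired_recovery_experiment(
    n_reps: int = 100,
    seed: int = 0,
    n_perm: int = 199,
    severities: tuple[int, int] = (15, 3),
    af_z_threshold: float = 1.2,
    ds_quantile: float = 0.15,
) -> dict[str, float]:
    """Paired two-cohort simulation of the adjustment pipelines.

    Each replicate builds one collection (6 planted, 8 housekeeping-decoy,
    26 background sets) with fixed per-pathway graphs, and two cohorts
    sharing the planted signal while housekeeping drift of different
    severity (``severities``, severe vs mild) inflates the decoys
    differently in each cohort. Per cohort: an equal-weight enrichment
    table (the base method); an AF-weighted re-analysis whose standardised
    scores, thresholded into a prioritised group (two-group weighted-BH),
    yield AF p-value weights; and density scores over the shared graphs
    (DE profile = top ``ds_quantile`` of |signal-to-noise|) as DS weights.

    Success fractions over replicates:
      * af_rank / ds_rank — planted sets achieve a strictly better mean
        rank after the AF / DS adjustment than in the base ranking;
      * af_corr / ds_corr — the cross-cohort Spearman correlation of the
        per-pathway p-values is at least as high after adjustment.
    Also returns the mean planted rank and mean correlations themselves.
    """
    rng = np.random.default_rng(seed)
    wins = {"af_rank": 0, "ds_rank": 0, "af_corr": 0, "ds_corr": 0}
    acc = {"base_corr": [], "af_corr_val": [], "ds_corr_val": [],
           "base_mean_rank": [], "af_mean_rank": [], "ds_mean_rank": []}
    for _ in range(n_reps):
        collection, planted, planted_de = _recovery_collection(rng)
        graphs = _recovery_graphs(rng, collection, planted_de)
        base_p, af_p, ds_p = [], [], []
        base_ranks, af_ranks, ds_ranks = [], [], []
        for n_drift in severities:
            dataset = _recovery_dataset(rng, collection, planted_de, n_drift)
            sub_seed = int(rng.integers(2**31))
            base = enrichment.enrichment_table(
                dataset, collection, n_perm=n_perm, seed=sub_seed,
                scheme="phenotype",
            )
            af_tab = af.run_af_analysis(
                dataset, collection, n_perm=n_perm, seed=sub_seed,
                scheme="phenotype",
            )
            af_scores = dict(zip(
                af_tab["pathway_id"],
                (af_tab["z_score"] >= af_z_threshold).astype(float),
            ))
            af_adj = adjust.adjust_base_method(
                base[["pathway_id", "score", "p_value"]], af_scores, "af"
            )
            profile = density.de_profile_from_ranked(
                enrichment.signal_to_noise(dataset), quantile=ds_quantile
            )
            ds_scores = {
                pid: density.pathway_density_score(gr, profile, decay=0.5
                                                   ).ds_pathway
                for pid, gr in graphs.items()
            }
            ds_adj = adjust.adjust_base_method(
                base[["pathway_id", "score", "p_value"]], ds_scores, "ds"
            )
            base_p.append(base.set_index("pathway_id")["p_value"])
            af_p.append(af_adj.set_index("pathway_id")["adjusted_p"])
            ds_p.append(ds_adj.set_index("pathway_id")["adjusted_p"])
            base_ranks.append(base.set_index("pathway_id")["rank"])
            af_ranks.append(af_adj.set_index("pathway_id")["rank"])
            ds_ranks.append(ds_adj.set_index("pathway_id")["rank"])

        def mean_planted(ranks: list[pd.Series]) -> float:
            return float(np.mean([r.loc[planted].mean() for r in ranks]))

        def pair_corr(vals: list[pd.Series]) -> float:
            joined = pd.concat(vals, axis=1, keys=["a", "b"])
            return float(sps.spearmanr(joined["a"], joined["b"]).statistic)

        base_mean = mean_planted(base_ranks)
        base_corr = pair_corr(base_p)
        wins["af_rank"] += mean_planted(af_ranks) < base_mean
        wins["ds_rank"] += mean_planted(ds_ranks) < base_mean
        wins["af_corr"] += pair_corr(af_p) >= base_corr
        wins["ds_corr"] += pair_corr(ds_p) >= base_corr
        acc["base_corr"].append(base_corr)
        acc["af_corr_val"].append(pair_corr(af_p))
        acc["ds_corr_val"].append(pair_corr(ds_p))
        acc["base_mean_rank"].append(base_mean)
        acc["af_mean_rank"].append(mean_planted(af_ranks))
        acc["ds_mean_rank"].append(mean_planted(ds_ranks))
    out = {k: v / n_reps for k, v in wins.items()}
    out.update({k: float(np.mean(v)) for k, v in acc.items()})
    return out
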