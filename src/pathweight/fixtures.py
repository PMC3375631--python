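"""Deterministic synthetic-data generators for every input kind.

The generators emulate the statistical structure the methods assume —
right-skewed gene-sharing across pathways (a few housekeeping-like genes in
many sets, most genes in one), two-class expression with planted
differential expression in chosen sets, and pathway graphs with DE genes
either clustered in one neighbourhood or dispersed across the graph — so
every property of the package can be exercised without external data.
Background expression is standard normal: the signal-to-noise ranking is
location-scale free, so any Gaussian background is equivalent for these
purposes; no claim of platform realism is made.

Every generator is a pure function of a :class:`FixtureSpec`: identical
specs yield byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    ExpressionDataset,
    GeneSet,
    PathwayCollection,
    PathwayGraph,
    ValidationError,
)
from . import io as pwio

#: per-generator salts so collection/expression/graph streams are independent
_SALT_COLLECTION = 11
_SALT_EXPRESSION = 23
_SALT_GRAPH = 37


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic scenario.

    ``sharing_profile`` maps an appearance count to the fraction of genes
    with that count (fractions should sum to ~1; the remainder goes to
    count 1). ``graph_model`` is one of path, cycle, erdos_renyi,
    barabasi_albert with ``graph_param`` as edge probability / attachment
    count. ``de_placement`` is clustered, dispersed or random.
    """

    seed: int = 0
    n_genes: int = 500
    n_samples_per_class: int = 10
    n_pathways: int = 20
    set_size_range: tuple[int, int] = (10, 60)
    sharing_profile: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.2, 3: 0.12, 5: 0.08, 10: 0.05}
    )
    de_fraction: float = 0.8
    effect_size: float = 1.0
    graph_model: str = "erdos_renyi"
    graph_param: float = 0.15
    graph_n_nodes: int = 30
    n_de: int = 6
    de_placement: str = "clustered"

    def __post_init__(self) -> None:
        if not 0.0 < self.de_fraction <= 1.0:
            raise ValidationError("de_fraction must lie in (0, 1]")
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi:
            raise ValidationError("invalid set_size_range")


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _target_counts(spec: FixtureSpec) -> list[int]:
    """Per-gene target appearance counts realising the sharing profile up
    to rounding (deterministic; remainder genes get count 1)."""
    counts: list[int] = []
    for c in sorted(spec.sharing_profile):
        frac = spec.sharing_profile[c]
        if c < 1:
            raise ValidationError(f"profile count {c} must be >= 1")
        # a gene can appear in at most every pathway
        counts.extend(
            [min(c, spec.n_pathways)] * int(round(frac * spec.n_genes))
        )
    if len(counts) > spec.n_genes:
        counts = counts[: spec.n_genes]
    counts.extend([1] * (spec.n_genes - len(counts)))
    return counts


def generate_collection(spec: FixtureSpec) -> PathwayCollection:
    """Generate a pathway collection whose per-gene appearance counts follow
    the sharing profile and whose set sizes fall in ``set_size_range``.

    Memberships are assigned greedily to the currently smallest sets so the
    realised sizes stay balanced; an infeasible profile (too many or too few
    memberships for the size range) raises.
    """
    rng = np.random.default_rng(spec.seed + _SALT_COLLECTION)
    genes = _gene_names(spec.n_genes)
    counts = _target_counts(spec)
    total = sum(counts)
    lo, hi = spec.set_size_range
    if total > spec.n_pathways * hi or total < spec.n_pathways * lo:
        raise ValidationError(
            f"sharing profile needs {total} memberships but set sizes allow "
            f"{spec.n_pathways * lo}..{spec.n_pathways * hi}"
        )
    order = rng.permutation(spec.n_genes)
    sizes = np.zeros(spec.n_pathways, dtype=int)
    members: list[set[str]] = [set() for _ in range(spec.n_pathways)]
    for gi in order:
        c = counts[gi]
        # distinct sets, smallest first, random tie-break
        pick = np.lexsort((rng.random(spec.n_pathways), sizes))[:c]
        for s in pick:
            members[s].add(genes[gi])
            sizes[s] += 1
    if sizes.min() < lo or sizes.max() > hi:
        raise ValidationError(
            f"realised set sizes {sizes.min()}..{sizes.max()} fall outside "
            f"{lo}..{hi}; profile and size range are inconsistent"
        )
    width = max(2, len(str(spec.n_pathways)))
    sets = tuple(
        GeneSet(f"P{i + 1:0{width}d}", f"synthetic pathway {i + 1}",
                frozenset(m))
        for i, m in enumerate(members)
    )
    return PathwayCollection(sets)


def generate_expression(
    spec: FixtureSpec,
    collection: PathwayCollection,
    enriched_set_ids: Sequence[str] = (),
) -> ExpressionDataset:
    """Two-class expression over the collection universe with planted
    signal: in each enriched set, a ``de_fraction`` of members gain a
    ``effect_size`` mean shift (in within-class sd units) in the first
    class. Classes are labelled 'case' and 'ctrl' ('case' sorts first)."""
    rng = np.random.default_rng(spec.seed + _SALT_EXPRESSION)
    known = set(collection.ids)
    bad = [i for i in enriched_set_ids if i not in known]
    if bad:
        raise ValidationError(f"enriched set id(s) not in collection: {bad}")
    genes = sorted(collection.universe)
    n_per = spec.n_samples_per_class
    samples = [f"s{i:03d}" for i in range(1, 2 * n_per + 1)]
    labels = pd.Series(
        ["case"] * n_per + ["ctrl"] * n_per, index=samples
    )
    values = rng.standard_normal((len(genes), 2 * n_per))
    gene_idx = {g: i for i, g in enumerate(genes)}
    shifted: set[str] = set()
    for sid in enriched_set_ids:
        mem = sorted(collection.get(sid).members)
        k = max(1, int(round(spec.de_fraction * len(mem))))
        chosen = rng.choice(len(mem), size=k, replace=False)
        shifted.update(mem[i] for i in chosen)
    for g in sorted(shifted):
        values[gene_idx[g], :n_per] += spec.effect_size
    frame = pd.DataFrame(values, index=genes, columns=samples)
    frame.index.name = "gene_id"
    return ExpressionDataset(frame, labels)


def _base_graph(spec: FixtureSpec, rng: np.random.Generator) -> nx.Graph:
    n = spec.graph_n_nodes
    if spec.graph_model == "path":
        return nx.path_graph(n)
    if spec.graph_model == "cycle":
        return nx.cycle_graph(n)
    if spec.graph_model == "erdos_renyi":
        for _ in range(200):
            g = nx.gnp_random_graph(
                n, spec.graph_param, seed=int(rng.integers(2**31))
            )
            if nx.is_connected(g):
                return g
        # join components with random bridge edges as a last resort
        comps = [sorted(c) for c in nx.connected_components(g)]
        for a, b in zip(comps, comps[1:]):
            g.add_edge(
                a[int(rng.integers(len(a)))], b[int(rng.integers(len(b)))]
            )
        return g
    if spec.graph_model == "barabasi_albert":
        m = max(1, int(spec.graph_param))
        return nx.barabasi_albert_graph(
            n, m, seed=int(rng.integers(2**31))
        )
    raise ValidationError(f"unknown graph model {spec.graph_model!r}")


def _clustered_nodes(
    g: nx.Graph, k: int, seed_node: int, rng: np.random.Generator
) -> list[int]:
    """Grow a k-node neighbourhood from the seed node breadth-first."""
    chosen = [seed_node]
    seen = {seed_node}
    frontier = [seed_node]
    while len(chosen) < k and frontier:
        nxt: list[int] = []
        for u in frontier:
            for v in sorted(g.neighbors(u)):
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
                    chosen.append(v)
                    if len(chosen) == k:
                        return chosen
        frontier = nxt
    while len(chosen) < k:  # disconnected leftovers: fill at random
        rest = sorted(set(g.nodes) - set(chosen))
        chosen.append(rest[int(rng.integers(len(rest)))])
    return chosen


def _dispersed_nodes(
    g: nx.Graph, k: int, rng: np.random.Generator
) -> list[int]:
    """Greedy farthest-point sampling on shortest-path distances."""
    nodes = sorted(g.nodes)
    dist = dict(nx.all_pairs_shortest_path_length(g))
    n = len(nodes)

    def d(u: int, v: int) -> float:
        return dist[u].get(v, n)  # unreachable treated as beyond-diameter

    chosen = [nodes[int(rng.integers(n))]]
    while len(chosen) < k:
        best, best_d = None, -1.0
        for u in nodes:
            if u in chosen:
                continue
            du = min(d(u, v) for v in chosen)
            if du > best_d:
                best, best_d = u, du
        chosen.append(best)
    return chosen


def generate_graph_with_de(
    spec: FixtureSpec,
    pathway_id: str = "P01",
    seed_node: int | None = None,
) -> tuple[PathwayGraph, dict[str, float]]:
    """Generate a pathway graph plus a binary DE profile over its nodes.

    Placement: ``clustered`` grows a breadth-first neighbourhood from a
    seed node; ``dispersed`` greedily maximises pairwise distance;
    ``random`` samples uniformly.
    """
    if spec.n_de > spec.graph_n_nodes:
        raise ValidationError(
            f"n_de={spec.n_de} exceeds graph size {spec.graph_n_nodes}"
        )
    rng = np.random.default_rng(spec.seed + _SALT_GRAPH)
    g = _base_graph(spec, rng)
    k = spec.n_de
    if k == spec.graph_n_nodes:
        de = list(g.nodes)
    elif spec.de_placement == "clustered":
        start = (
            seed_node if seed_node is not None
            else int(rng.integers(spec.graph_n_nodes))
        )
        de = _clustered_nodes(g, k, start, rng)
    elif spec.de_placement == "dispersed":
        de = _dispersed_nodes(g, k, rng)
    elif spec.de_placement == "random":
        de = [sorted(g.nodes)[i]
              for i in rng.choice(spec.graph_n_nodes, size=k, replace=False)]
    else:
        raise ValidationError(
            f"unknown de_placement {spec.de_placement!r}"
        )
    width = max(2, len(str(spec.graph_n_nodes)))
    name = {u: f"g{u + 1:0{width}d}" for u in g.nodes}
    graph = PathwayGraph.from_edges(
        pathway_id,
        [(name[a], name[b]) for a, b in g.edges],
        extra_nodes=name.values(),
    )
    profile = {name[u]: (1.0 if u in set(de) else 0.0) for u in g.nodes}
    return graph, profile


def write_fixture_bundle(
    spec: FixtureSpec,
    out_dir: str | Path,
    enriched_set_ids: Sequence[str] = (),
    n_graphs: int = 2,
) -> dict[str, Path]:
    """Generate and write a complete input bundle: GMT collection,
    expression + labels TSVs, per-pathway edge lists and a DE profile.

    Graph i uses seed ``spec.seed + i`` and the spec's placement; files are
    byte-identical across runs for the same spec.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collection = generate_collection(spec)
    if not enriched_set_ids:
        enriched_set_ids = collection.ids[:1]
    dataset = generate_expression(spec, collection, enriched_set_ids)
    paths = {
        "gmt": out / "collection.gmt",
        "matrix": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "de_profile": out / "de_profile.tsv",
        "graphs": out / "graphs",
    }
    pwio.write_gmt(collection, paths["gmt"])
    pwio.write_expression(dataset, paths["matrix"], paths["labels"])
    paths["graphs"].mkdir(exist_ok=True)
    profile_union: dict[str, float] = {}
    for i in range(n_graphs):
        gspec = replace(spec, seed=spec.seed + i)
        pid = f"P{i + 1:02d}"
        graph, profile = generate_graph_with_de(gspec, pathway_id=pid)
        # keep node names distinct across pathways
        renamed = {f"{pid}_{g}": v for g, v in profile.items()}
        graph = PathwayGraph.from_edges(
            pid,
            [(f"{pid}_{a}", f"{pid}_{b}") for a, b in graph.edges],
            extra_nodes=[f"{pid}_{g}" for g in graph.nodes],
        )
        pwio.write_edge_list(graph, paths["graphs"] / f"{pid}.tsv")
        profile_union.update(renamed)
    pwio.write_de_profile(profile_union, paths["de_profile"])
    return paths
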