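import numpy as np
import networkx as nx
import pytest

from pathweight import density
from pathweight.containers import PathwayGraph, RankedList, ValidationError


class TestAllPairsShortestPaths:
    def test_path_graph_distances(self):
        g = PathwayGraph.from_edges("P", [("A", "B"), ("B", "C")])
        dm = density.all_pairs_shortest_paths(g)
        assert dm.distance("A", "C") == 2
        assert dm.distance("A", "B") == 1
        assert all(dm.distance(x, x) == 0 for x in "ABC")

    def test_disconnected_pair_unreachable(self):
        g = PathwayGraph.from_edges("P", [("A", "B"), ("C", "D")])
        dm = density.all_pairs_shortest_paths(g)
        assert dm.distance("A", "C") == density.UNREACHABLE

    def test_empty_graph_rejected(self):
        g = PathwayGraph("P", frozenset(), frozenset())
        with pytest.raises(ValidationError):
            density.all_pairs_shortest_paths(g)

    def test_matches_bfs_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for gi in range(50):
            n = int(rng.integers(2, 40))
            g = nx.gnp_random_graph(
                n, float(rng.uniform(0.05, 0.3)),
                seed=int(rng.integers(2**31)),
            )
            names = {u: f"n{u:02d}" for u in g.nodes}
            pg = PathwayGraph.from_edges(
                f"G{gi}",
                [(names[a], names[b]) for a, b in g.edges],
                extra_nodes=names.values(),
            )
            dm = density.all_pairs_shortest_paths(pg)
            for i, src in enumerate(dm.order):
                lengths = nx.single_source_shortest_path_length(
                    g, int(src[1:])
                )
                for j, dst in enumerate(dm.order):
                    want = lengths.get(int(dst[1:]), density.UNREACHABLE)
                    assert dm.d[i, j] == want


class TestGeneDensityScore:
    def test_path6_hand_enumeration(self, p6_graph, p6_clustered):
        dm = density.all_pairs_shortest_paths(p6_graph)
        ds2 = density.gene_density_score("g2", dm, p6_clustered, decay=0.5)
        ds1 = density.gene_density_score("g1", dm, p6_clustered, decay=0.5)
        ds5 = density.gene_density_score("g5", dm, p6_clustered, decay=0.5)
        assert ds2 == pytest.approx(1.0)     # 0.5 + 0.5 from g1, g3
        assert ds1 == pytest.approx(0.75)    # 0.5 + 0.25 from g2, g3
        assert ds5 == pytest.approx(0.0)     # not differentially expressed

    def test_zero_intensity_gene_scores_zero(self, p6_graph):
        dm = density.all_pairs_shortest_paths(p6_graph)
        profile = {f"g{i}": 1.0 for i in range(1, 7)}
        profile["g3"] = 0.0
        assert density.gene_density_score("g3", dm, profile, 0.5) == 0.0

    def test_isolated_de_gene_scores_zero(self):
        g = PathwayGraph.from_edges(
            "P", [("A", "B")], extra_nodes=["Z"]
        )
        dm = density.all_pairs_shortest_paths(g)
        profile = {"A": 1.0, "B": 1.0, "Z": 1.0}
        assert density.gene_density_score("Z", dm, profile, 0.5) == 0.0

    def test_decay_bounds_validated(self, p6_graph, p6_clustered):
        dm = density.all_pairs_shortest_paths(p6_graph)
        for bad in (0.0, 1.0, 1.5, -0.1):
            with pytest.raises(ValidationError, match=r"\(0, 1\)"):
                density.gene_density_score("g1", dm, p6_clustered, bad)


class TestPathwayDensityScore:
    def test_clustered_configuration(self, p6_graph, p6_clustered):
        res = density.pathway_density_score(p6_graph, p6_clustered, 0.5)
        assert res.ds_pathway == pytest.approx((0.75 + 1.0 + 0.75) / 6)

    def test_dispersed_configuration(self, p6_graph, p6_dispersed):
        res = density.pathway_density_score(p6_graph, p6_dispersed, 0.5)
        assert res.ds_pathway == pytest.approx((0.3125 + 0.5 + 0.3125) / 6)

    def test_all_zero_profile(self, p6_graph):
        res = density.pathway_density_score(
            p6_graph, {f"g{i}": 0.0 for i in range(1, 7)}, 0.5
        )
        assert res.ds_pathway == 0.0

    def test_monotone_in_decay(self, p6_graph, p6_clustered):
        scores = [
            density.pathway_density_score(
                p6_graph, p6_clustered, d
            ).ds_pathway
            for d in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_adding_adjacent_de_gene_never_decreases(self, p6_graph):
        rng = np.random.default_rng(2)
        for _ in range(20):
            flags = rng.integers(0, 2, size=6).astype(float)
            if flags.sum() == 0:
                flags[0] = 1.0
            profile = {f"g{i + 1}": flags[i] for i in range(6)}
            before = density.pathway_density_score(
                p6_graph, profile, 0.5
            ).ds_pathway
            # flag a neighbour of an existing DE gene
            de = [i for i in range(6) if flags[i] > 0]
            i = de[0]
            nb = i + 1 if i < 5 else i - 1
            profile2 = dict(profile)
            profile2[f"g{nb + 1}"] = 1.0
            after = density.pathway_density_score(
                p6_graph, profile2, 0.5
            ).ds_pathway
            assert after >= before - 1e-12

    def test_isomorphism_invariance(self, p6_graph, p6_clustered):
        mapping = {f"g{i}": f"x{7 - i}" for i in range(1, 7)}
        relabeled = PathwayGraph.from_edges(
            "P6r",
            [(mapping[a], mapping[b]) for a, b in p6_graph.edges],
            extra_nodes=[mapping[g] for g in p6_graph.nodes],
        )
        prof2 = {mapping[g]: v for g, v in p6_clustered.items()}
        a = density.pathway_density_score(p6_graph, p6_clustered, 0.5)
        b = density.pathway_density_score(relabeled, prof2, 0.5)
        assert a.ds_pathway == pytest.approx(b.ds_pathway)

    def test_inverse_penalty_mode(self, p6_graph, p6_clustered):
        res = density.pathway_density_score(
            p6_graph, p6_clustered, decay=0.5, penalty="inverse"
        )
        # g2: 1/1 + 1/1; g1: 1/1 + 1/2; g3 symmetric to g1
        assert res.ds_pathway == pytest.approx((1.5 + 2.0 + 1.5) / 6)


class TestDeProfile:
    def test_binary_top_quantile(self):
        ranked = RankedList(
            [f"g{i}" for i in range(10)],
            np.linspace(2.0, 0.1, 10),
        )
        profile = density.de_profile_from_ranked(ranked, quantile=0.2)
        assert profile["g0"] == 1.0 and profile["g1"] == 1.0
        assert sum(profile.values()) == 2

    def test_binary_uses_absolute_statistic(self):
        ranked = RankedList(["a", "b", "c", "d"], [1.0, 0.2, 0.1, -3.0])
        profile = density.de_profile_from_ranked(ranked, quantile=0.25)
        assert profile["d"] == 1.0

    def test_continuous_mode_scales_to_unit(self):
        ranked = RankedList(["a", "b", "c"], [2.0, 1.0, -4.0])
        profile = density.de_profile_from_ranked(ranked, mode="continuous")
        assert profile["c"] == 1.0
        assert profile["a"] == pytest.approx(0.5)


class TestRunDsAnalysis:
    def test_clustered_ranks_above_dispersed(
        self, p6_graph, p6_clustered, p6_dispersed
    ):
        other = PathwayGraph.from_edges(
            "Q6", [(f"h{i}", f"h{i + 1}") for i in range(1, 6)]
        )
        prof = dict(p6_clustered)
        prof.update({f"h{i}": p6_dispersed[f"g{i}"] for i in range(1, 7)})
        table, results = density.run_ds_analysis([p6_graph, other], prof)
        ranks = dict(zip(table["pathway_id"], table["rank"]))
        assert ranks == {"P6": 1, "Q6": 2}
        assert results["P6"].ds_pathway > results["Q6"].ds_pathway

    def test_single_pathway_rank_one(self, p6_graph, p6_dispersed):
        table, _ = density.run_ds_analysis([p6_graph], p6_dispersed)
        assert list(table["rank"]) == [1]

    def test_duplicate_structure_tie_broken_by_id(
        self, p6_graph, p6_clustered
    ):
        twin = PathwayGraph.from_edges("A6", sorted(p6_graph.edges))
        table, _ = density.run_ds_analysis([p6_graph, twin], p6_clustered)
        ranks = dict(zip(table["pathway_id"], table["rank"]))
        assert ranks == {"A6": 1, "P6": 2}

    def test_pathway_absent_from_profile_scores_zero(
        self, p6_graph, p6_clustered, caplog
    ):
        import logging

        other = PathwayGraph.from_edges("ZZ", [("y1", "y2")])
        with caplog.at_level(logging.WARNING):
            table, results = density.run_ds_analysis(
                [p6_graph, other], p6_clustered
            )
        assert results["ZZ"].ds_pathway == 0.0
        assert "ZZ" in caplog.text
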