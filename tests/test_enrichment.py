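import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pathweight import enrichment
from pathweight.containers import (
    GeneSet,
    PathwayCollection,
    RankedList,
    ValidationError,
)
from conftest import make_dataset


def brute_force_es(genes, members, weights=None, convention="extreme"):
    """Independent reference: materialise the full running sum in plain
    Python and scan for the extreme (first peak wins)."""
    present = [g for g in genes if g in members]
    n, nh = len(genes), len(present)
    if weights is None:
        wf = lambda g: 1.0
    else:
        wmax = max(weights[g] for g in present)
        wf = lambda g: weights[g] / wmax
    wtot = sum(wf(g) for g in present)
    running, total = [], 0.0
    for g in genes:
        total += wf(g) / wtot if g in members else -1.0 / (n - nh)
        running.append(total)
    values = [abs(v) for v in running] if convention == "extreme" else running
    top = max(values)
    best = next(
        i for i, v in enumerate(values)
        if v >= top - enrichment.PEAK_TIE_TOL
    )
    return running[best], best + 1


class TestSignalToNoise:
    def test_direct_formula(self):
        frame = pd.DataFrame(
            [[2.5, 1.5, 1.5, 0.5]],
            index=["G1"],
            columns=["s1", "s2", "s3", "s4"],
        )
        # case mean 2.0 sd ~0.707, ctrl mean 1.0 sd ~0.707
        from pathweight.containers import ExpressionDataset
        ds = ExpressionDataset(
            frame,
            pd.Series(["case", "case", "ctrl", "ctrl"],
                      index=["s1", "s2", "s3", "s4"]),
        )
        stat = enrichment.signal_to_noise_values(ds)[0]
        sd = np.std([2.5, 1.5], ddof=1)
        assert stat == pytest.approx((2.0 - 1.0) / (2 * sd))

    def test_equal_means_score_zero(self):
        frame = pd.DataFrame(
            [[1.0, 3.0, 3.0, 1.0]],
            index=["G1"], columns=["s1", "s2", "s3", "s4"],
        )
        from pathweight.containers import ExpressionDataset
        ds = ExpressionDataset(
            frame,
            pd.Series(["case", "case", "ctrl", "ctrl"],
                      index=["s1", "s2", "s3", "s4"]),
        )
        assert enrichment.signal_to_noise_values(ds)[0] == 0.0

    def test_sorted_descending_with_gene_tiebreak(self, small_dataset):
        ranked = enrichment.signal_to_noise(small_dataset)
        assert list(ranked.stats) == sorted(ranked.stats, reverse=True)

    def test_constant_gene_does_not_crash(self):
        ds = make_dataset(n_genes=3)
        ds.values.iloc[0] = 5.0  # zero variance, nonzero mean
        ds.values.iloc[1] = 0.0  # zero variance, zero mean
        stats = enrichment.signal_to_noise_values(ds)
        assert np.all(np.isfinite(stats))

    @settings(max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance_of_ranking(self, scale):
        ds = make_dataset(seed=3)
        ranked = enrichment.signal_to_noise(ds)
        ds.values *= scale
        assert enrichment.signal_to_noise(ds).genes == ranked.genes


class TestRunningSum:
    def test_top_gene_set(self, four_gene_ranked):
        es = enrichment.running_sum_es(four_gene_ranked, {"g1"})
        assert es.es == pytest.approx(1.0)
        assert es.peak_index == 1

    def test_bottom_gene_set(self, four_gene_ranked):
        es = enrichment.running_sum_es(four_gene_ranked, {"g4"})
        assert es.es == pytest.approx(-1.0)
        assert es.peak_index == 3

    def test_constant_weights_match_equal(self, four_gene_ranked):
        equal = enrichment.running_sum_es(four_gene_ranked, {"g1", "g3"})
        scaled = enrichment.running_sum_es(
            four_gene_ranked, {"g1", "g3"},
            weights={g: 7.3 for g in "g1 g2 g3 g4".split()},
        )
        assert scaled.es == pytest.approx(equal.es)
        assert scaled.peak_index == equal.peak_index

    def test_empty_intersection_error(self, four_gene_ranked):
        with pytest.raises(ValidationError, match="not represented"):
            enrichment.running_sum_es(four_gene_ranked, {"zz"})

    def test_full_coverage_error(self, four_gene_ranked):
        with pytest.raises(ValidationError, match="entire ranked list"):
            enrichment.running_sum_es(
                four_gene_ranked, {"g1", "g2", "g3", "g4"}
            )

    def test_all_zero_weights_error(self, four_gene_ranked):
        with pytest.raises(ValidationError, match="zero-weight"):
            enrichment.running_sum_es(
                four_gene_ranked, {"g1", "g3"},
                weights={"g1": 0.0, "g3": 0.0},
            )

    def test_max_convention_picks_maximum(self, four_gene_ranked):
        es = enrichment.running_sum_es(
            four_gene_ranked, {"g4"}, convention="max"
        )
        # running sum is (-1/3, -2/3, -1, 0); maximum is the final 0
        assert es.es == pytest.approx(0.0)
        assert es.peak_index == 4

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = int(rng.integers(2, 21))
            genes = [f"g{i}" for i in range(n)]
            ranked = RankedList(genes, np.sort(rng.standard_normal(n))[::-1])
            k = int(rng.integers(1, min(8, n - 1) + 1))
            members = set(
                genes[i] for i in rng.choice(n, size=k, replace=False)
            )
            weights = (
                {g: float(rng.uniform(0.1, 3)) for g in genes}
                if rng.random() < 0.5 else None
            )
            conv = "extreme" if rng.random() < 0.5 else "max"
            got = enrichment.running_sum_es(
                ranked, members, weights=weights, convention=conv
            )
            want_es, want_peak = brute_force_es(genes, members, weights, conv)
            assert got.es == pytest.approx(want_es, abs=1e-12)
            assert got.peak_index == want_peak


class TestPermutationPvalues:
    def test_add_one_bounds(self):
        null = np.linspace(0.1, 0.5, 99)[None, :]
        above_all = enrichment.pvalues_from_null(np.array([0.9]), null)
        below_all = enrichment.pvalues_from_null(np.array([0.01]), null)
        assert above_all[0] == pytest.approx(1 / 100)
        assert below_all[0] == pytest.approx(1.0)

    def test_deterministic_given_seed(self, small_dataset):
        gs = GeneSet("S", "s", frozenset(["G001", "G005", "G009"]))
        p1 = enrichment.permutation_pvalue(
            small_dataset, gs, n_perm=50, seed=4, scheme="gene_set"
        )
        p2 = enrichment.permutation_pvalue(
            small_dataset, gs, n_perm=50, seed=4, scheme="gene_set"
        )
        assert p1 == p2

    def test_auto_scheme_uses_gene_set_for_tiny_classes(self, small_dataset):
        coll = PathwayCollection(
            (GeneSet("S", "s", frozenset(["G001", "G005", "G009"])),)
        )
        # 4 per class < 7: must not crash and must be reproducible
        t1 = enrichment.enrichment_table(
            small_dataset, coll, n_perm=30, seed=1, scheme="auto"
        )
        t2 = enrichment.enrichment_table(
            small_dataset, coll, n_perm=30, seed=1, scheme="auto"
        )
        pd.testing.assert_frame_equal(t1, t2)


class TestBhFdr:
    def test_hand_computed_stepup(self):
        q = enrichment.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_pvalue(self):
        assert enrichment.bh_fdr([1.0])[0] == 1.0

    @settings(max_examples=50, derandomize=True)
    @given(
        p=st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                   max_size=30)
    )
    def test_q_at_least_p(self, p):
        q = enrichment.bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            enrichment.bh_fdr([0.5, 1.5])


class TestRankTable:
    def test_score_descending(self):
        t = pd.DataFrame({"pathway_id": ["P1", "P2"], "score": [0.2, 0.9]})
        out = enrichment.rank_table(t, key="score_desc")
        assert dict(zip(out["pathway_id"], out["rank"])) == {"P2": 1, "P1": 2}

    def test_ties_broken_by_pathway_id(self):
        t = pd.DataFrame({"pathway_id": ["P2", "P1"], "score": [0.5, 0.5]})
        out = enrichment.rank_table(t, key="score_desc")
        assert dict(zip(out["pathway_id"], out["rank"])) == {"P1": 1, "P2": 2}

    def test_pvalue_ascending(self):
        t = pd.DataFrame(
            {"pathway_id": ["P1", "P2"], "p_value": [0.04, 0.01]}
        )
        out = enrichment.rank_table(t, key="p_asc")
        assert dict(zip(out["pathway_id"], out["rank"])) == {"P2": 1, "P1": 2}

    def test_missing_key_rejected(self):
        t = pd.DataFrame({"pathway_id": ["P1"], "score": [0.2]})
        with pytest.raises(ValidationError):
            enrichment.rank_table(t, key="p_asc")
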