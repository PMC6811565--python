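"""Disease signatures, network distances, degree-preserving nulls, Fisher tests."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from coexpharm.pharmacology import (
    GraphIndex,
    NullDistribution,
    Signature,
    degree_preserving_sample,
    disease_signature,
    drug_disease_proximity,
    fisher_exact_2x2,
    lcc_size,
    mean_shortest_distance_ds,
    min_relevant_count,
    proximity_screen,
    rank_drugs,
    signature_agglomeration,
    validate_lists,
    zscore,
)
from coexpharm.synthetic import simulate_drugs, simulate_interactome
from coexpharm.types import DrugRecord, Interactome


def make_interactome(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return Interactome(graph=g)


class TestDiseaseSignature:
    @staticmethod
    def _table(gs, gc):
        return pd.DataFrame(
            {
                "gs_consensus": gs,
                "gc_consensus": gc,
                "meta_module": 1,
            },
            index=pd.Index([f"g{i}" for i in range(len(gs))], name="gene"),
        )

    def test_quantile_zero_requests_whole_module(self, path_interactome):
        table = self._table(np.linspace(0, 1, 6), np.linspace(0, 1, 6))
        table.index = pd.Index([f"n{i}" for i in range(6)], name="gene")
        sig = disease_signature(table, 1, path_interactome, quantile=0.0)
        assert sig.requested == set(table.index)

    def test_aligned_ranks_pass_top_two_at_80th_percentile(self):
        # 10 genes, gs ranks = gc ranks: exactly the top 2 clear both cutoffs
        gs = np.arange(10) / 10
        inter = make_interactome([(f"g{i}", f"g{j}") for i, j in itertools.combinations(range(10), 2)])
        sig = disease_signature(self._table(gs, 2 * gs), 1, inter, quantile=0.8)
        assert sig.requested == {"g8", "g9"}

    def test_anti_ranked_scores_yield_empty_signature_error(self):
        gs = np.arange(10) / 10
        inter = make_interactome([("g0", "g1")])
        with pytest.raises(ValueError, match="need >= 2"):
            disease_signature(self._table(gs, 2 - 2 * gs), 1, inter, quantile=0.8)


class TestGraphDistances:
    def test_lcc_of_adjacent_and_scattered_signatures(self):
        inter = make_interactome([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
        assert lcc_size(inter, Signature({"a", "b"}, {"a", "b"})) == 2
        assert lcc_size(inter, Signature({"a", "c"}, {"a", "c"})) == 1  # induced subgraph

    def test_mean_shortest_distance_examples(self, path_interactome):
        sig = Signature({"n0", "n2"}, {"n0", "n2"})
        assert mean_shortest_distance_ds(path_interactome, sig) == 2.0
        adj = Signature({"n0", "n1"}, {"n0", "n1"})
        assert mean_shortest_distance_ds(path_interactome, adj) == 1.0

    def test_clique_signature_distance_one(self):
        inter = make_interactome(itertools.combinations("abcd", 2))
        sig = Signature(set("abcd"), set("abcd"))
        assert mean_shortest_distance_ds(inter, sig) == 1.0

    def test_proximity_examples_on_path(self, path_interactome):
        sig = Signature({"n0", "n1"}, {"n0", "n1"})
        drug = DrugRecord("D", "d", {"n3", "n5"})
        # distances to nearest signature node: 2 and 4
        assert drug_disease_proximity(path_interactome, drug, sig) == 3.0
        inside = DrugRecord("D2", "d2", {"n0", "n1"})
        assert drug_disease_proximity(path_interactome, inside, sig) == 0.0

    def test_adding_a_zero_distance_target_decreases_proximity(self, path_interactome):
        sig = Signature({"n0", "n1"}, {"n0", "n1"})
        far = DrugRecord("D", "d", {"n4"})
        near = DrugRecord("D", "d", {"n4", "n0"})
        assert drug_disease_proximity(path_interactome, near, sig) < drug_disease_proximity(
            path_interactome, far, sig
        )

    def test_distances_match_all_pairs_oracle(self):
        inter, truth = simulate_interactome(150, 2, 10, seed=1)
        gi = GraphIndex(inter)
        sig_nodes = set(list(truth.disease_neighborhood)[:6])
        sig = Signature(sig_nodes, sig_nodes)
        apsp = dict(nx.all_pairs_shortest_path_length(inter.graph))
        # <d_s> oracle
        expect = np.mean(
            [min(apsp[u][v] for v in sig_nodes if v != u) for u in sig_nodes]
        )
        assert mean_shortest_distance_ds(gi, sig) == pytest.approx(expect)
        # <d_c> oracle for a random drug
        drug = DrugRecord("D", "d", set(sorted(inter.nodes)[:5]))
        expect_dc = np.mean(
            [min(apsp[t][v] for v in sig_nodes) for t in drug.targets]
        )
        assert drug_disease_proximity(gi, drug, sig) == pytest.approx(expect_dc)


class TestDegreePreservingSample:
    def test_singleton_bins_preserve_degree_multiset(self):
        # star-plus-path graph: many distinct degrees
        edges = [("h", f"x{i}") for i in range(6)] + [("x0", "x1"), ("x1", "x2")]
        inter = make_interactome(edges)
        gi = GraphIndex(inter)
        ref = gi.idx({"h", "x0", "x5"})
        sample = degree_preserving_sample(gi, ref, seed=0, min_bin_size=1)
        assert sorted(gi.degrees[sample]) == sorted(gi.degrees[ref])

    def test_reference_equal_to_all_nodes_returns_all(self):
        inter, _ = simulate_interactome(60, 2, 5, seed=2)
        gi = GraphIndex(inter)
        ref = np.arange(gi.n)
        sample = degree_preserving_sample(gi, ref, seed=1, min_bin_size=10)
        np.testing.assert_array_equal(sample, ref)

    def test_mean_degree_tracks_reference_over_draws(self):
        # for uniformly drawn references the degree-matched sample is
        # marginally uniform, so the grand mean degrees must agree
        inter, _ = simulate_interactome(500, 3, 20, seed=3)
        gi = GraphIndex(inter)
        rng = np.random.default_rng(4)
        bins = gi.degree_bins(25)
        ref_means, samp_means = [], []
        for _ in range(1000):
            ref = rng.choice(gi.n, size=20, replace=False)
            samp = degree_preserving_sample(gi, ref, rng, 25, bins=bins)
            ref_means.append(gi.degrees[ref].mean())
            samp_means.append(gi.degrees[samp].mean())
        assert abs(np.mean(samp_means) - np.mean(ref_means)) < 0.1 * np.mean(ref_means)

    def test_samples_are_distinct_nodes(self):
        inter, _ = simulate_interactome(100, 2, 10, seed=5)
        gi = GraphIndex(inter)
        sample = degree_preserving_sample(gi, np.arange(30), seed=6, min_bin_size=10)
        assert len(np.unique(sample)) == 30


class TestZscore:
    def test_at_the_mean_and_two_sigma(self):
        null = NullDistribution("s", [1.0, 2.0, 3.0])
        z, _ = zscore(2.0, null)
        assert z == 0.0
        z2, _ = zscore(2.0 + 2 * null.sigma, null)
        assert z2 == pytest.approx(2.0)

    def test_population_sigma_convention(self):
        null = NullDistribution("s", [1.0, 2.0, 3.0])
        assert null.sigma == pytest.approx(math.sqrt(2.0 / 3.0))
        z, _ = zscore(3.0, null)
        assert z == pytest.approx(1.2247448, rel=1e-6)

    def test_statistic_inside_degenerate_null_is_zero_or_error(self):
        null = NullDistribution("s", [5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="zero sigma"):
            zscore(5.0, null)
        spread = NullDistribution("s", [4.0, 5.0, 6.0])
        z, p = zscore(5.0, spread)
        assert z == 0.0 and p > 0


@pytest.fixture(scope="module")
def planted_world():
    inter, truth = simulate_interactome(1200, 3, 20, seed=7)
    drugs = simulate_drugs(inter, truth, 8, 8, 3, seed=8)
    gi = GraphIndex(inter)
    sig = Signature(truth.disease_neighborhood, truth.disease_neighborhood, "planted")
    return gi, truth, drugs, sig


class TestAgglomeration:
    def test_planted_neighborhood_is_agglomerated(self, planted_world):
        gi, truth, _, sig = planted_world
        out = signature_agglomeration(gi, sig, n_reps=300, seed=9, min_bin_size=25)
        assert out["S"]["z"] > 2
        assert out["d_s"]["z"] < 0

    def test_random_signature_is_not_agglomerated(self):
        # near-regular graph so the degree-matched null is well calibrated
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(40 + seed)
            g = nx.random_regular_graph(4, 300, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
            gi = GraphIndex(Interactome(graph=g))
            nodes = {f"v{i}" for i in rng.choice(300, size=15, replace=False)}
            sig = Signature(nodes, nodes)
            out = signature_agglomeration(gi, sig, n_reps=200, seed=seed, min_bin_size=25)
            ok += abs(out["S"]["z"]) < 2
        assert ok >= 8

    def test_single_rep_null_rejected(self, planted_world):
        gi, _, _, sig = planted_world
        with pytest.raises(ValueError, match="n_reps"):
            signature_agglomeration(gi, sig, n_reps=1, seed=0)


class TestProximityScreen:
    def test_proximal_below_distal_and_deterministic(self, planted_world):
        gi, truth, drugs, sig = planted_world
        res = proximity_screen(gi, drugs, sig, n_reps=200, seed=10, min_bin_size=25)
        z = {r.drug_id: r.z for r in res}
        prox = [z[d] for d in z if truth.drug_class[d] == "proximal"]
        dist = [z[d] for d in z if truth.drug_class[d] == "distal"]
        assert np.mean(prox) < np.mean(dist)
        assert all(v < 0 for v in prox)
        res2 = proximity_screen(gi, drugs, sig, n_reps=200, seed=10, min_bin_size=25)
        assert [r.z for r in res2] == [r.z for r in res]

    def test_result_independent_of_drug_order(self, planted_world):
        gi, _, drugs, sig = planted_world
        res_fwd = proximity_screen(gi, drugs, sig, n_reps=50, seed=11, min_bin_size=25)
        res_rev = proximity_screen(gi, drugs[::-1], sig, n_reps=50, seed=11, min_bin_size=25)
        assert {r.drug_id: r.z for r in res_fwd} == {r.drug_id: r.z for r in res_rev}


class TestRankDrugs:
    @staticmethod
    def _result(drug_id, d_c, z):
        from coexpharm.pharmacology import ProximityResult
        return ProximityResult(drug_id, drug_id, d_c, z, 0.0, 1)

    def test_top_k_are_smallest_z_when_all_eligible(self):
        results = [self._result(f"D{i:02d}", 0.5, float(i)) for i in range(100)]
        top, _ = rank_drugs(results, dc_quantile=1.0, k=10)
        assert [r.drug_id for r in top] == [f"D{i:02d}" for i in range(10)]

    def test_low_z_but_distant_drug_is_excluded(self):
        results = [self._result(f"D{i:02d}", 1.0, float(i + 1)) for i in range(20)]
        results.append(self._result("FAR", 9.0, -5.0))
        top, bottom = rank_drugs(results, dc_quantile=0.5, k=5)
        assert "FAR" not in [r.drug_id for r in top]
        assert "FAR" in [r.drug_id for r in bottom]

    def test_z_ties_broken_by_smaller_dc_then_id(self):
        results = [
            self._result("B", 0.4, 1.0),
            self._result("A", 0.2, 1.0),
            self._result("C", 0.2, 1.0),
        ]
        top, _ = rank_drugs(results, dc_quantile=1.0, k=3)
        assert [r.drug_id for r in top] == ["A", "C", "B"]


class TestFisherExact:
    def test_worked_examples(self):
        p_two, _ = fisher_exact_2x2([[9, 1], [3, 7]])
        assert p_two == pytest.approx(0.019766611, rel=1e-6)
        p_cat, p_cat_one = fisher_exact_2x2([[9, 1], [42, 1791]])
        assert p_cat == pytest.approx(4.4945942e-14, rel=1e-6)
        assert p_cat_one == pytest.approx(p_cat, rel=1e-9)  # opposite tail is heavier

    def test_symmetric_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]])[0] == pytest.approx(1.0)

    def test_matches_brute_force_enumeration_small_tables(self):
        def oracle(a, b, c, d):
            r1, c1, n = a + b, a + c, a + b + c + d
            probs = {}
            for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
                probs[x] = (
                    math.comb(r1, x) * math.comb(n - r1, c1 - x) / math.comb(n, c1)
                )
            obs = probs[a]
            return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))

        rng = np.random.default_rng(12)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 15, size=4)
            got, _ = fisher_exact_2x2([[a, b], [c, d]])
            assert got == pytest.approx(oracle(int(a), int(b), int(c), int(d)), rel=1e-9)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 30, size=4)
            got_two, got_one = fisher_exact_2x2([[a, b], [c, d]])
            assert got_two == pytest.approx(
                scipy_fisher([[a, b], [c, d]]).pvalue, rel=1e-8
            )
            assert got_one == pytest.approx(
                scipy_fisher([[a, b], [c, d]], alternative="greater").pvalue, rel=1e-8
            )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            fisher_exact_2x2([[0, 0], [3, 7]])

    def test_catalogue_break_even_count(self):
        # how relevant the catalogue must be before a 9/10 top list loses significance
        assert min_relevant_count(9, 1, 1833, 0.01) == 893


class TestValidateLists:
    def test_truth_labelled_hits_favour_top_list(self, planted_world):
        gi, truth, drugs, sig = planted_world
        hits = {d.drug_id: truth.drug_class[d.drug_id] == "proximal" for d in drugs}
        report = validate_lists(
            gi, drugs, sig, hits, seed=14, n_reps=100, k=5, min_bin_size=25,
            dc_quantile=0.5,
        )
        assert report["hit_counts"]["top"] >= report["hit_counts"]["random_by_dc"]

    def test_all_hits_give_p_one(self, planted_world):
        gi, _, drugs, sig = planted_world
        hits = {d.drug_id: True for d in drugs}
        report = validate_lists(
            gi, drugs, sig, hits, seed=15, n_reps=50, k=5, min_bin_size=25
        )
        assert report["fisher"]["top_vs_random_dc"][0] == pytest.approx(1.0)

    def test_same_seed_reproduces_random_lists(self, planted_world):
        gi, truth, drugs, sig = planted_world
        hits = {d.drug_id: truth.drug_class[d.drug_id] == "proximal" for d in drugs}
        a = validate_lists(gi, drugs, sig, hits, seed=16, n_reps=50, k=5, min_bin_size=25)
        b = validate_lists(gi, drugs, sig, hits, seed=16, n_reps=50, k=5, min_bin_size=25)
        assert a["random_by_dc"] == b["random_by_dc"]
        assert a["random_by_z"] == b["random_by_z"]
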