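"""Adjacency, soft-threshold selection, TOM, consensus, module detection."""

import numpy as np
import pytest
from scipy import stats

from coexpharm.coexpression import (
    cluster_modules,
    connectivity,
    consensus,
    consensus_tom_dissimilarity,
    pick_beta,
    signed_adjacency,
    tom,
    tom_dissimilarity,
)
from coexpharm.types import SymmetricGeneMatrix, UNASSIGNED_LABEL

from conftest import make_dataset


def tom_triple_loop(a):
    """Brute-force reference for the topological overlap."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1.0
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[j, u] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) - a[i, j] + 1.0)
    return out


def random_adjacency(rng, n):
    m = rng.uniform(0, 1, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return SymmetricGeneMatrix([f"g{i}" for i in range(n)], m, role="adjacency")


class TestSignedAdjacency:
    def test_closed_forms_at_extreme_correlations(self):
        t = np.linspace(0, 1, 8)
        vals = np.vstack([t, t, 1 - t])  # cor(0,1)=1, cor(0,2)=-1
        ds = make_dataset(vals)
        adj = signed_adjacency(ds, beta=7.0)
        assert adj.values[0, 1] == pytest.approx(1.0)
        assert adj.values[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_at_beta_20(self):
        # orthogonal vectors: A = 0.5^20
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        ds = make_dataset(np.vstack([x, y]))
        adj = signed_adjacency(ds, beta=20.0)
        assert adj.values[0, 1] == pytest.approx(0.5**20, rel=1e-9)

    def test_monotone_in_correlation(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.normal(size=(20, 30)))
        corr = np.corrcoef(ds.values)
        adj = signed_adjacency(ds, beta=6.0)
        iu = np.triu_indices(20, 1)
        order_c = np.argsort(corr[iu])
        assert (np.diff(adj.values[iu][order_c]) >= 0).all()

    def test_constant_gene_named_in_error(self):
        vals = np.random.default_rng(1).normal(size=(3, 6))
        vals[1] = 2.5
        with pytest.raises(ValueError, match="g1"):
            signed_adjacency(make_dataset(vals), beta=2.0)


class TestConnectivity:
    def test_sums_off_diagonal_entries(self):
        m = np.array([[1.0, 0.2, 0.3], [0.2, 1.0, 1.0], [0.3, 1.0, 1.0]])
        adj = SymmetricGeneMatrix(list("abc"), m, role="adjacency")
        np.testing.assert_allclose(connectivity(adj), [0.5, 1.2, 1.3])

    def test_complete_and_empty_graphs(self):
        ones = np.ones((3, 3))
        adj = SymmetricGeneMatrix(list("abc"), ones, role="adjacency")
        np.testing.assert_allclose(connectivity(adj), [2, 2, 2])
        adj0 = SymmetricGeneMatrix(list("abc"), np.eye(3), role="adjacency")
        np.testing.assert_allclose(connectivity(adj0), [0, 0, 0])


class TestPickBeta:
    def test_power_law_connectivities_fit_well(self):
        # regression oracle on exact power-law counts, via the same binning
        from coexpharm.coexpression import _scale_free_r2
        rng = np.random.default_rng(2)
        k = rng.pareto(1.5, size=5000) + 1.0
        assert _scale_free_r2(np.log(k + 1) * 0 + k, n_bins=10) > 0.8

    def test_single_candidate_is_returned(self, small_dataset):
        rng = np.random.default_rng(3)
        ds = make_dataset(rng.normal(size=(60, 12)))
        fit = pick_beta(ds, candidates=[20], r2_min=0.0)
        assert fit.beta == 20

    def test_uniform_connectivities_flagged(self):
        from coexpharm.coexpression import _scale_free_r2
        k = np.linspace(1, 100, 1000)  # uniform: flat bin frequencies
        assert _scale_free_r2(k, n_bins=10) < 0.3

    def test_smallest_passing_beta_selected(self):
        datasets, _ = _planted(seed=4)
        fit = pick_beta(datasets[0], candidates=list(range(1, 15)), r2_min=0.8)
        table = fit.table
        passing = table[table["r_squared"] >= 0.8]
        if len(passing):
            assert fit.beta == passing["beta"].iloc[0]
            assert fit.reached_threshold
        else:
            assert not fit.reached_threshold


class TestTOM:
    def test_two_node_closed_form(self):
        m = np.array([[1.0, 1.0], [1.0, 1.0]])
        adj = SymmetricGeneMatrix(list("ab"), m, role="adjacency")
        assert tom(adj).values[0, 1] == pytest.approx(1.0)

    def test_disconnected_nodes_have_zero_overlap(self):
        adj = SymmetricGeneMatrix(list("abc"), np.eye(3), role="adjacency")
        t = tom(adj).values
        assert t[np.triu_indices(3, 1)].max() == 0.0

    def test_complete_triangle_closed_form(self):
        m = np.ones((3, 3))
        adj = SymmetricGeneMatrix(list("abc"), m, role="adjacency")
        np.testing.assert_allclose(tom(adj).values, np.ones((3, 3)))

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            adj = random_adjacency(rng, 50)
            expected = tom_triple_loop(adj.values)
            got = tom(adj).values
            assert np.abs(got - expected).max() < 1e-10

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            t = tom(random_adjacency(rng, 30)).values
            assert t.min() >= 0.0 and t.max() <= 1.0

    def test_dissimilarity_complements_tom(self):
        rng = np.random.default_rng(7)
        t = tom(random_adjacency(rng, 20))
        d = tom_dissimilarity(t)
        off = ~np.eye(20, dtype=bool)
        np.testing.assert_allclose(d.values[off], 1.0 - t.values[off])
        assert np.diag(d.values).max() == 0.0


class TestConsensus:
    @staticmethod
    def _mats(arrays, role="tom"):
        genes = [f"g{i}" for i in range(arrays[0].shape[0])]
        return [SymmetricGeneMatrix(genes, a, role=role) for a in arrays]

    def test_min_median_mean_operators(self):
        a = np.full((2, 2), 0.2); np.fill_diagonal(a, 1)
        b = np.full((2, 2), 0.7); np.fill_diagonal(b, 1)
        c = np.full((2, 2), 0.5); np.fill_diagonal(c, 1)
        mats = self._mats([a, b, c])
        assert consensus(mats, "min").values[0, 1] == pytest.approx(0.2)
        assert consensus(mats, "median").values[0, 1] == pytest.approx(0.5)
        assert consensus(mats, "mean").values[0, 1] == pytest.approx(0.2 / 3 + 0.7 / 3 + 0.5 / 3)

    def test_idempotent_on_identical_inputs(self):
        rng = np.random.default_rng(8)
        m = random_adjacency(rng, 10)
        out = consensus([m, m, m], "min")
        np.testing.assert_allclose(out.values, m.values)

    def test_min_is_elementwise_lower_bound_and_permutation_equivariant(self):
        rng = np.random.default_rng(9)
        mats = [random_adjacency(rng, 15) for _ in range(4)]
        out = consensus(mats, "min")
        for m in mats:
            assert (out.values <= m.values + 1e-15).all()
        out2 = consensus(mats[::-1], "min")
        np.testing.assert_array_equal(out.values, out2.values)

    def test_mismatched_gene_lists_rejected(self):
        rng = np.random.default_rng(10)
        a, b = random_adjacency(rng, 5), random_adjacency(rng, 5)
        b.gene_ids = [f"x{i}" for i in range(5)]
        with pytest.raises(ValueError, match="gene list"):
            consensus([a, b], "min")

    def test_orientation_min_on_similarity(self):
        # a pair strongly co-expressed in only one tissue must NOT be
        # consensus-similar; the literal min-on-dissimilarity variant says it is
        strong = np.full((2, 2), 0.9); np.fill_diagonal(strong, 1)
        weak = np.full((2, 2), 0.05); np.fill_diagonal(weak, 1)
        mats = self._mats([strong, weak])
        default = consensus_tom_dissimilarity(mats)
        literal = consensus_tom_dissimilarity(mats, literal_min_dissim=True)
        assert default.values[0, 1] == pytest.approx(0.95)   # dissimilar
        assert literal.values[0, 1] == pytest.approx(0.1)    # similar


def _planted(seed, n_genes=300, module_sizes=(50, 50), within_cor=0.6):
    from coexpharm.synthetic import simulate_multitissue
    return simulate_multitissue(4, n_genes, 20, list(module_sizes), within_cor, 0.0, seed=seed)


class TestClusterModules:
    @staticmethod
    def _block_dissim(sizes, within=0.2, between=0.9, seed=0):
        n = sum(sizes)
        rng = np.random.default_rng(seed)
        d = np.full((n, n), between) + rng.uniform(-0.02, 0.02, size=(n, n))
        start = 0
        for s in sizes:
            d[start : start + s, start : start + s] = within + rng.uniform(
                -0.02, 0.02, size=(s, s)
            )
            start += s
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        return SymmetricGeneMatrix([f"g{i}" for i in range(n)], d, role="dissimilarity")

    def test_two_planted_blocks_recovered_exactly(self):
        dis = self._block_dissim([50, 50])
        part = cluster_modules(dis, min_module_size=30)
        assert len(part.module_ids) == 2
        first = set(part.members(part.labels[0]))
        assert first == set(dis.gene_ids[:50])

    def test_structureless_matrix_leaves_all_unassigned(self):
        n = 60
        d = np.ones((n, n)) - np.eye(n)
        dis = SymmetricGeneMatrix([f"g{i}" for i in range(n)], d, role="dissimilarity")
        part = cluster_modules(dis, min_module_size=30)
        assert part.n_assigned() == 0

    def test_permutation_equivariance(self):
        dis = self._block_dissim([40, 40, 40], seed=3)
        part = cluster_modules(dis, min_module_size=30)
        rng = np.random.default_rng(4)
        perm = rng.permutation(dis.n)
        dis2 = SymmetricGeneMatrix(
            [dis.gene_ids[i] for i in perm], dis.values[np.ix_(perm, perm)], "dissimilarity"
        )
        part2 = cluster_modules(dis2, min_module_size=30)
        by_gene1 = dict(zip(part.gene_ids, part.labels))
        by_gene2 = dict(zip(part2.gene_ids, part2.labels))
        # same partition up to relabeling: co-membership agrees for all pairs
        genes = part.gene_ids
        for a, b in zip(genes[:-1], genes[1:]):
            assert (by_gene1[a] == by_gene1[b]) == (by_gene2[a] == by_gene2[b])

    def test_fewer_genes_than_min_size_warns_and_unassigns(self, caplog):
        d = self._block_dissim([10])
        with caplog.at_level("WARNING"):
            part = cluster_modules(d, min_module_size=30)
        assert part.n_assigned() == 0

    def test_consensus_pipeline_recovers_planted_modules(self):
        from coexpharm.coexpression import consensus_modules
        datasets, truth = _planted(seed=11)
        part, _ = consensus_modules(datasets)
        planted = truth.planted_module_genes()
        for genes in planted.values():
            best = max(
                len(genes & set(part.members(m))) / len(genes | set(part.members(m)))
                for m in part.module_ids
            )
            assert best >= 0.8
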