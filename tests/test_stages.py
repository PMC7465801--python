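"""Processing stages: normalization identities, regression against a
normal-equations oracle, deviance against termwise hand computation, PCA
properties, neighbor graphs against a brute-force oracle, clustering."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pipegrid.stages import (
    NormalizedMatrix,
    binomial_deviance,
    build_neighbor_graph,
    cluster_graph,
    filter_features_by_type,
    lognormalize,
    pca_embed,
    quick_cluster,
    rank_features,
    scale_features,
)


class TestLognormalize:
    def test_two_gene_arithmetic(self):
        out = lognormalize(np.array([[10.0], [0.0]]), scale_target=10)
        assert out.values[0, 0] == pytest.approx(np.log1p(10))
        assert out.values[1, 0] == 0.0

    def test_size_factor_invariance(self):
        X = np.array([[4, 8], [6, 12], [0, 0]], dtype=float)
        out = lognormalize(X)
        assert np.allclose(out.values[:, 0], out.values[:, 1])

    def test_zero_gene_row_stays_zero(self):
        out = lognormalize(np.array([[5, 5], [0, 0]], dtype=float))
        assert np.all(out.values[1] == 0)

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            lognormalize(np.array([[1, 0], [1, 0]], dtype=float))


class TestScale:
    def test_rows_have_zero_mean_unit_variance(self):
        rng = np.random.default_rng(0)
        Z = scale_features(rng.normal(size=(20, 50)))
        assert np.allclose(Z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(Z.var(axis=1, ddof=1), 1, atol=1e-12)

    def test_gene_linear_in_covariate_becomes_zero(self):
        cov = np.linspace(0, 1, 30)
        X = np.vstack([2 + 3 * cov, np.random.default_rng(1).normal(size=30)])
        Z = scale_features(X, covariates=cov)
        assert np.allclose(Z[0], 0, atol=1e-9)

    def test_residuals_match_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 40))
        C = rng.normal(size=(40, 2))
        D = np.column_stack([np.ones(40), C])
        resid_oracle = X - (D @ np.linalg.solve(D.T @ D, D.T @ X.T)).T
        Z = scale_features(X, covariates=C)
        Z_oracle = scale_features(resid_oracle)
        assert np.allclose(Z, Z_oracle, atol=1e-9)

    def test_zero_variance_gene_row_zeroed(self):
        Z = scale_features(np.vstack([np.full(10, 7.0), np.arange(10.0)]))
        assert np.all(Z[0] == 0)


class TestRankFeatures:
    def test_constant_proportion_gene_has_zero_deviance(self):
        # gene 0 takes exactly half of every cell's library
        Y = np.array([[5, 10, 20], [3, 6, 12], [2, 4, 8]], dtype=float)
        dev = binomial_deviance(Y)
        assert dev[0] == pytest.approx(0.0, abs=1e-9)

    def test_deviance_matches_termwise_hand_oracle(self):
        Y = np.array([[3, 0, 1, 4], [1, 2, 5, 0], [2, 2, 2, 2]], dtype=float)
        n = Y.sum(axis=0)
        pi = Y.sum(axis=1) / n.sum()

        def hand_dev(g):
            tot = 0.0
            for i in range(4):
                y, ni = Y[g, i], n[i]
                if y > 0:
                    tot += y * np.log(y / (ni * pi[g]))
                if ni - y > 0:
                    tot += (ni - y) * np.log((ni - y) / (ni * (1 - pi[g])))
            return 2 * tot

        dev = binomial_deviance(Y)
        for g in range(3):
            assert dev[g] == pytest.approx(hand_dev(g), rel=1e-9)

    def test_constant_gene_ranked_last_by_variance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 30))
        X[4] = 2.5
        r = rank_features(X, "variance")
        assert r.order[-1] == 4 and r.values[4] == 0

    def test_mean_expression_invariant_to_cell_permutation(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 40))
        r1 = rank_features(X, "mean_expression")
        r2 = rank_features(X[:, rng.permutation(40)], "mean_expression")
        assert np.array_equal(r1.order, r2.order)

    def test_standardized_variance_downweights_high_mean_genes(self):
        rng = np.random.default_rng(5)
        n = 300
        # Poisson-like mean-variance coupling, one genuinely variable gene
        means = np.exp(rng.uniform(0, 3, 50))
        X = rng.poisson(means[:, None], size=(50, n)).astype(float)
        X[7] = rng.poisson(np.where(rng.random(n) < 0.5, 2.0, 40.0))
        r = rank_features(X, "standardized_variance")
        assert r.order[0] == 7

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            rank_features(np.zeros((3, 3)), "magic")


class TestFeatureTypeFilter:
    def test_exclusions_match_set_difference_oracle(self, sim3):
        gm = sim3.gene_meta
        expect = set(gm.index) - set(gm.index[gm["is_mito"]])
        out = filter_features_by_type(sim3, exclude=("mito",))
        assert set(out.gene_meta.index) == expect
        out3 = filter_features_by_type(sim3, exclude=("mito", "ribo", "noncoding"))
        expect3 = set(
            gm.index[~(gm["is_mito"] | gm["is_ribo"] | ~gm["is_coding"])]
        )
        assert set(out3.gene_meta.index) == expect3

    def test_exclude_none_is_identity(self, sim3):
        out = filter_features_by_type(sim3, exclude=())
        assert out.counts.shape == sim3.counts.shape

    def test_emptying_exclusion_rejected(self, sim3):
        all_flagged = sim3.subset_genes(
            sim3.gene_meta["is_mito"].to_numpy(dtype=bool)
        )
        with pytest.raises(ValueError, match="every gene"):
            filter_features_by_type(all_flagged, exclude=("mito",))


class TestPCA:
    def test_variances_non_increasing_and_reconstruction(self):
        rng = np.random.default_rng(6)
        # rank-8 signal: components beyond it capture nothing and the
        # embedding's column space spans the whole centered matrix
        X = rng.normal(size=(20, 8)) @ rng.normal(size=(8, 30))
        Z = scale_features(X)
        emb = pca_embed(Z, n_components=12)
        assert np.all(np.diff(emb.variances) <= 1e-9)
        Zc = (Z - Z.mean(axis=1, keepdims=True)).T  # cells x genes
        U = emb.coords
        proj = U @ np.linalg.lstsq(U, Zc, rcond=None)[0]
        assert np.allclose(proj, Zc, atol=1e-8)

    def test_weighted_column_norms_proportional_to_singular_values(self):
        rng = np.random.default_rng(7)
        Z = scale_features(rng.normal(size=(25, 40)))
        w = pca_embed(Z, 5, weight_by_variance=True)
        u = pca_embed(Z, 5, weight_by_variance=False)
        norms_w = np.linalg.norm(w.coords, axis=0)
        s = np.sqrt(w.variances * (40 - 1))
        assert np.allclose(norms_w, s, rtol=1e-9)
        assert np.allclose(np.var(u.coords, axis=0, ddof=1), 1.0, rtol=1e-9)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(8)
        Z = scale_features(rng.normal(size=(30, 50)))
        a = pca_embed(Z, 5)
        b = pca_embed(Z.copy(), 5)
        assert np.allclose(a.coords, b.coords)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pca_embed(np.zeros((5, 5)), 10)


class TestNeighborGraph:
    def test_knn_edges_match_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(30, 4))
        k = 5
        A = build_neighbor_graph(pts, k=k, graph_type="knn")
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(D, np.inf)
        expected = set()
        for i in range(30):
            for j in np.argsort(D[i])[:k]:
                expected.add((min(i, j), max(i, j)))
        got = set(zip(*sp.triu(A, k=1).nonzero()))
        assert got == expected

    def test_two_blobs_give_two_components(self):
        rng = np.random.default_rng(10)
        pts = np.vstack(
            [rng.normal(0, 0.1, (20, 3)), rng.normal(10, 0.1, (20, 3))]
        )
        A = build_neighbor_graph(pts, k=4, graph_type="knn")
        from scipy.sparse.csgraph import connected_components

        n_comp, _ = connected_components(A, directed=False)
        assert n_comp == 2

    def test_snn_jaccard_identical_neighborhoods_weight_one(self):
        # two coincident points share all neighbors (incl. each other)
        pts = np.array(
            [[0, 0], [0, 0], [1, 0], [0, 1], [1, 1], [5, 5], [5, 6], [6, 5]],
            dtype=float,
        )
        A = build_neighbor_graph(pts, k=3, graph_type="snn_jaccard")
        assert A[0, 1] == pytest.approx(1.0)

    def test_snn_rank_weights_bounded_by_k(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(40, 3))
        A = build_neighbor_graph(pts, k=6, graph_type="snn_rank")
        assert A.data.max() <= 6

    def test_unknown_graph_type(self):
        with pytest.raises(ValueError):
            build_neighbor_graph(np.zeros((10, 2)), k=2, graph_type="mystery")


class TestClusterGraph:
    @pytest.mark.parametrize(
        "method", ["modularity_resolution", "walk_based", "greedy_modularity"]
    )
    def test_two_disconnected_cliques(self, method):
        A = sp.lil_matrix((10, 10))
        for grp in (range(5), range(5, 10)):
            for i in grp:
                for j in grp:
                    if i < j:
                        A[i, j] = A[j, i] = 1.0
        labels = cluster_graph(A.tocsr(), method, seed=0)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:5])) == 1

    def test_resolution_sweep_nondecreasing_cluster_count(self):
        rng = np.random.default_rng(12)
        pts = np.vstack([rng.normal(c, 0.4, (30, 3)) for c in (0, 4, 8)])
        A = build_neighbor_graph(pts, k=8)
        ks = [
            len(np.unique(cluster_graph(A, resolution=r, seed=1)))
            for r in (0.01, 0.1, 1.0, 4.0)
        ]
        assert all(a <= b for a, b in zip(ks, ks[1:]))

    def test_singleton_graph(self):
        labels = cluster_graph(sp.csr_matrix((1, 1)), "modularity_resolution")
        assert labels.tolist() == [0]

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            cluster_graph(sp.csr_matrix((0, 0)))

    def test_seeded_determinism(self):
        rng = np.random.default_rng(13)
        pts = np.vstack([rng.normal(c, 0.5, (40, 3)) for c in (0, 5)])
        A = build_neighbor_graph(pts, k=6)
        a = cluster_graph(A, resolution=0.5, seed=42)
        b = cluster_graph(A, resolution=0.5, seed=42)
        assert np.array_equal(a, b)


class TestEndToEnd:
    def test_default_stage_chain_recovers_subpopulations(self, sim3):
        from pipegrid.metrics import ari, contingency

        norm = lognormalize(sim3.counts)
        top = rank_features(norm, "variance").order[:500]
        Z = scale_features(NormalizedMatrix(norm.values[top], norm.size_factors))
        emb = pca_embed(Z, 10)
        A = build_neighbor_graph(emb, k=15)
        labels = cluster_graph(A, resolution=0.1, seed=0)
        singlet = ~sim3.cell_meta["is_doublet"].to_numpy()
        truth = sim3.cell_meta["phenoid"].to_numpy()
        score = ari(contingency(truth[singlet], labels[singlet]))
        assert score >= 0.8

    def test_quick_cluster_separates_subpopulations(self, sim3):
        labels = quick_cluster(sim3, seed=0)
        from pipegrid.metrics import mutual_information, contingency

        truth = sim3.cell_meta["phenoid"].to_numpy()
        mi = mutual_information(contingency(truth, labels))
        assert mi > 0.5
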