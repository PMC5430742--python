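import numpy as np
import pytest

from conftest import hard_indicator, random_partition
from netbc.biclustering import (
    NetBC,
    extract_biclusters,
    fit_biclustering,
    initialize_indicators,
    objective,
    residue_decomposition,
    top_biclusters,
    update_C,
    update_R,
)
from netbc.simulate import make_checkerboard


def blockwise_ssr(G, row_labels, col_labels, w=None):
    """Brute-force oracle: explicit group means, double loop over blocks."""
    w = np.ones(G.shape[0]) if w is None else w
    total = 0.0
    for a in np.unique(row_labels):
        I = np.where(row_labels == a)[0]
        for b in np.unique(col_labels):
            J = np.where(col_labels == b)[0]
            S = G[np.ix_(I, J)]
            H = (
                S
                - S.mean(axis=1, keepdims=True)
                - S.mean(axis=0, keepdims=True)
                + S.mean()
            )
            total += float((w[I, None] * H * H).sum())
    return total


class TestObjective:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_blockwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(8, 51))
        n = int(rng.integers(6, 21))
        k = int(rng.integers(2, 6))
        d = int(rng.integers(2, 5))
        G = rng.standard_normal((m, n))
        rl = random_partition(rng, m, k)
        cl = random_partition(rng, n, d)
        w = rng.uniform(0.2, 2.0, m)
        got = objective(G, hard_indicator(rl, k), hard_indicator(cl, d), w)
        want = blockwise_ssr(G, rl, cl, w)
        assert got == pytest.approx(want, rel=1e-10)

    def test_zero_on_blockwise_additive_data(self, rng):
        # g_ij = u + alpha_i + beta_j inside every checkerboard block
        rl = np.repeat([0, 1, 2], 4)
        cl = np.repeat([0, 1], 4)
        G = np.empty((12, 8))
        for a in range(3):
            for b in range(2):
                blk = np.ix_(rl == a, cl == b)
                u = rng.normal()
                alpha = rng.normal(size=((rl == a).sum(), 1))
                beta = rng.normal(size=(1, (cl == b).sum()))
                G[blk] = u + alpha + beta
        val = objective(G, hard_indicator(rl, 3), hard_indicator(cl, 2))
        assert val < 1e-18

    def test_doubling_one_weight_adds_that_rows_residue(self, rng):
        G = rng.standard_normal((12, 8))
        rl = random_partition(rng, 12, 3)
        cl = random_partition(rng, 8, 2)
        R, C = hard_indicator(rl, 3), hard_indicator(cl, 2)
        w = np.ones(12)
        base = objective(G, R, C, w)
        H = residue_decomposition(G, R, C)["residual"]
        w2 = w.copy()
        w2[4] = 2.0
        assert objective(G, R, C, w2) == pytest.approx(
            base + (H[4] ** 2).sum(), rel=1e-10
        )

    def test_group_mean_identity(self, rng):
        # the projected matrix equals per-column means over each row cluster
        G = rng.standard_normal((15, 6))
        rl = random_partition(rng, 15, 4)
        R = hard_indicator(rl, 4)
        row_mean = residue_decomposition(G, R, hard_indicator(np.zeros(6, int), 1))[
            "row_mean"
        ]
        for a in range(4):
            I = np.where(rl == a)[0]
            expected = G[I].mean(axis=0)
            for i in I:
                np.testing.assert_allclose(row_mean[i], expected, atol=1e-12)

    def test_k1_d1_closed_form(self, rng):
        G = rng.standard_normal((9, 7))
        w = rng.uniform(0.5, 1.5, 9)
        H = G - G.mean(1, keepdims=True) - G.mean(0, keepdims=True) + G.mean()
        want = float((w[:, None] * H * H).sum())
        got = objective(G, np.ones((9, 1)), np.ones((7, 1)), w)
        assert got == pytest.approx(want, rel=1e-10)

    def test_permutation_equivariance(self, rng):
        G = rng.standard_normal((14, 6))
        w = rng.uniform(0.5, 2.0, 14)
        rl = random_partition(rng, 14, 3)
        cl = random_partition(rng, 6, 2)
        R, C = hard_indicator(rl, 3), hard_indicator(cl, 2)
        perm = rng.permutation(14)
        assert objective(G[perm], R[perm], C, w[perm]) == pytest.approx(
            objective(G, R, C, w), rel=1e-12
        )


class TestUpdates:
    @pytest.mark.parametrize("seed", range(50))
    def test_single_update_decreases_objective(self, seed):
        rng = np.random.default_rng(seed)
        G = rng.standard_normal((20, 10))
        R, C = initialize_indicators(G, 3, 2, "random", rng)
        w = rng.uniform(0.2, 2.0, 20)
        before = objective(G, R, C, w)
        assert objective(G, update_R(G, R, C, w), C, w) <= before + 1e-9
        assert objective(G, R, update_C(G, R, C, w), w) <= before + 1e-9

    def test_uniform_weights_match_omitted_weights(self, rng):
        G = rng.standard_normal((15, 8))
        R, C = initialize_indicators(G, 3, 2, "random", rng)
        np.testing.assert_allclose(
            update_R(G, R, C, None), update_R(G, R, C, np.ones(15)), rtol=1e-12
        )
        np.testing.assert_allclose(
            update_C(G, R, C, None), update_C(G, R, C, np.ones(15)), rtol=1e-12
        )

    def test_fixed_point_of_converged_solution(self):
        # after convergence on clean data the multiplicative factor is ~1
        expr, rl, cl = make_checkerboard(30, 20, 3, 2, kind="constant", seed=5)
        res = fit_biclustering(
            expr.values, 3, 2, init="kmeans", random_state=5, max_iter=300
        )
        R2 = update_R(expr.values, res.R, res.C, res.weights)
        R2 = R2 / R2.sum(1, keepdims=True)
        assert np.max(np.abs(R2 - res.R)) < 1e-6


class TestInitialize:
    def test_random_rows_sum_to_one(self, rng):
        R, C = initialize_indicators(rng.standard_normal((10, 6)), 3, 2, "random", 0)
        np.testing.assert_allclose(R.sum(1), 1.0)
        np.testing.assert_allclose(C.sum(1), 1.0)

    def test_same_seed_identical(self, rng):
        G = rng.standard_normal((12, 6))
        for method in ("random", "kmeans"):
            R1, C1 = initialize_indicators(G, 3, 2, method, 42)
            R2, C2 = initialize_indicators(G, 3, 2, method, 42)
            np.testing.assert_array_equal(R1, R2)
            np.testing.assert_array_equal(C1, C2)

    def test_kmeans_hardens_duplicated_row_blocks(self, rng):
        block = rng.standard_normal((1, 6))
        G = np.vstack([np.tile(block, (5, 1)), np.tile(block + 10.0, (5, 1))])
        R, _ = initialize_indicators(G, 2, 2, "kmeans", 0)
        labels = np.argmax(R, axis=1)
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_bad_cluster_counts_rejected(self, rng):
        G = rng.standard_normal((5, 4))
        with pytest.raises(ValueError):
            initialize_indicators(G, 6, 2, "random", 0)
        with pytest.raises(ValueError):
            initialize_indicators(G, 2, 5, "random", 0)


class TestFit:
    def test_recovers_clean_checkerboard(self):
        from netbc.metrics import rand_score

        expr, rl, cl = make_checkerboard(60, 30, 3, 2, kind="constant", seed=1)
        res = fit_biclustering(expr.values, 3, 2, init="kmeans", random_state=1)
        assert rand_score(rl, res.row_labels) == 1.0
        assert rand_score(cl, res.col_labels) == 1.0
        assert res.objective_trace[-1] < 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_trace_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        G = rng.standard_normal((30, 15))
        res = fit_biclustering(G, 3, 2, random_state=seed, max_iter=100)
        assert np.all(np.diff(res.objective_trace) <= 1e-9)

    def test_deterministic_under_seed(self, rng):
        G = rng.standard_normal((25, 12))
        r1 = fit_biclustering(G, 3, 2, random_state=7, max_iter=50)
        r2 = fit_biclustering(G, 3, 2, random_state=7, max_iter=50)
        np.testing.assert_array_equal(r1.row_labels, r2.row_labels)
        np.testing.assert_array_equal(r1.objective_trace, r2.objective_trace)

    def test_all_clusters_populated_after_repair(self, rng):
        G = rng.standard_normal((20, 10))
        res = fit_biclustering(G, 5, 3, random_state=0, max_iter=50)
        assert set(res.row_labels) == set(range(5))
        assert set(res.col_labels) == set(range(3))


class TestExtraction:
    def test_all_blocks_cover_matrix_once(self, rng):
        rl = random_partition(rng, 12, 3)
        cl = random_partition(rng, 8, 2)
        blocks = extract_biclusters(rl, cl)
        assert len(blocks) == 6
        count = np.zeros((12, 8), dtype=int)
        for bc in blocks:
            for i in bc.genes:
                for j in bc.samples:
                    count[i, j] += 1
        assert (count == 1).all()

    def test_top_blocks_rank_coherent_first(self, rng):
        expr, rl, cl = make_checkerboard(30, 20, 3, 2, kind="constant", seed=9)
        G = expr.values + rng.normal(0, 0.01, expr.values.shape)
        top = top_biclusters(G, rl, cl, 2)
        assert len(top) == 2
        full = extract_biclusters(rl, cl)
        assert all(bc in full for bc in top)


class TestEstimator:
    def test_sklearn_api(self):
        expr, rl, cl = make_checkerboard(40, 20, 3, 2, seed=3)
        model = NetBC(3, 2, init="kmeans", random_state=3)
        assert model.get_params()["n_row_clusters"] == 3
        model.fit(expr.values)
        assert model.row_labels_.shape == (40,)
        assert model.column_labels_.shape == (20,)
        assert model.rows_.shape == (6, 40)
        assert model.columns_.shape == (6, 20)
        assert len(model.get_biclusters_()) == 6

    def test_clone_and_set_params(self):
        from sklearn.base import clone

        model = NetBC(4, 3, theta=0.5, random_state=1)
        other = clone(model)
        assert other.get_params() == model.get_params()
        other.set_params(n_row_clusters=2)
        assert other.n_row_clusters == 2

    def test_theta_without_network_rejected(self, rng):
        with pytest.raises(ValueError, match="network"):
            NetBC(2, 2, theta=0.5).fit(rng.standard_normal((10, 6)))

    def test_accepts_expression_matrix_and_frame(self, small_expr):
        model = NetBC(2, 2, random_state=0, max_iter=20).fit(small_expr)
        blocks = model.get_biclusters_()
        genes = set().union(*(bc.genes for bc in blocks))
        assert genes == set(small_expr.gene_ids)
        model2 = NetBC(2, 2, random_state=0, max_iter=20).fit(small_expr.to_frame())
        np.testing.assert_array_equal(model.row_labels_, model2.row_labels_)
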