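import numpy as np
import pytest

from conftest import hard_indicator
from netbc.biclustering import objective
from netbc.simulate import (
    PATTERN_KINDS,
    ImplantSpec,
    add_noise,
    generate_background,
    generate_structured_network,
    implant,
    inject_noisy_genes,
    make_checkerboard,
    make_implanted_dataset,
    perturb_network,
)


class TestBackground:
    def test_moments_near_standard_normal(self):
        G = generate_background(100, 100, seed=0)
        assert abs(G.mean()) < 4 / np.sqrt(G.size)
        assert abs(G.var() - 1.0) < 0.06

    def test_seed_determinism(self):
        np.testing.assert_array_equal(
            generate_background(10, 5, seed=3), generate_background(10, 5, seed=3)
        )


class TestImplant:
    def spec(self, kind, sigma=0.0):
        return ImplantSpec(
            kind=kind,
            row_sets=[[0, 1, 2], [5, 6, 7]],
            col_sets=[[0, 1, 2, 3], [4, 5, 6, 7]],
            sigma_noise=sigma,
            seed=11,
        )

    def test_constant_block_has_zero_variance(self, rng):
        G, truth = implant(rng.standard_normal((10, 9)), self.spec("constant"))
        sub = G[np.ix_([0, 1, 2], [0, 1, 2, 3])]
        assert sub.std() == 0.0
        assert len(truth) == 2

    def test_row_constant_columns_identical(self, rng):
        G, _ = implant(rng.standard_normal((10, 9)), self.spec("row_constant"))
        sub = G[np.ix_([5, 6, 7], [4, 5, 6, 7])]
        assert np.ptp(sub, axis=1).max() == 0.0

    def test_column_constant_rows_identical(self, rng):
        G, _ = implant(rng.standard_normal((10, 9)), self.spec("column_constant"))
        sub = G[np.ix_([0, 1, 2], [0, 1, 2, 3])]
        assert np.ptp(sub, axis=0).max() == 0.0

    def test_additive_block_has_zero_residue(self, rng):
        G, _ = implant(rng.standard_normal((10, 9)), self.spec("additive"))
        sub = G[np.ix_([0, 1, 2], [0, 1, 2, 3])]
        H = sub - sub.mean(1, keepdims=True) - sub.mean(0, keepdims=True) + sub.mean()
        assert np.abs(H).max() < 1e-12

    def test_cells_outside_implants_untouched(self, rng):
        base = rng.standard_normal((10, 9))
        G, truth = implant(base, self.spec("constant"))
        mask = np.zeros_like(base, dtype=bool)
        for bc in truth:
            mask[np.ix_(sorted(bc.genes), sorted(bc.samples))] = True
        np.testing.assert_array_equal(G[~mask], base[~mask])

    def test_overlapping_specs_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            ImplantSpec(
                kind="constant",
                row_sets=[[0, 1], [1, 2]],
                col_sets=[[0], [1]],
            )


class TestAddNoise:
    def test_sigma_zero_is_identity(self, rng):
        G = rng.standard_normal((8, 5))
        np.testing.assert_array_equal(add_noise(G, 0.0, seed=1), G)

    def test_noise_std_matches_sigma(self, rng):
        G = rng.standard_normal((100, 80))
        diff = add_noise(G, 0.2, seed=2) - G
        assert abs(diff.std() - 0.2) < 0.01

    def test_different_seeds_differ(self, rng):
        G = rng.standard_normal((8, 5))
        assert not np.array_equal(add_noise(G, 0.1, 1), add_noise(G, 0.1, 2))


class TestMakeImplantedDataset:
    def test_default_geometry(self):
        expr, truth, spec = make_implanted_dataset(seed=0)
        assert expr.shape == (100, 50)
        assert len(truth) == 3
        assert all(len(bc.genes) == 15 and len(bc.samples) == 8 for bc in truth)

    def test_truth_uses_expression_ids(self):
        expr, truth, _ = make_implanted_dataset(seed=1)
        gene_ids = set(expr.gene_ids)
        for bc in truth:
            assert bc.genes <= gene_ids


class TestMakeCheckerboard:
    @pytest.mark.parametrize("kind", PATTERN_KINDS[:4])
    def test_noiseless_truth_partition_has_zero_residue(self, kind):
        expr, rl, cl = make_checkerboard(40, 24, 3, 2, kind=kind, sigma=0.0, seed=2)
        val = objective(expr.values, hard_indicator(rl, 3), hard_indicator(cl, 2))
        assert val < 1e-12

    def test_block_means_override(self):
        mu = np.array([[5.0, -5.0], [-5.0, 5.0]])
        expr, rl, cl = make_checkerboard(
            20, 10, 2, 2, kind="constant", seed=0, block_means=mu, within=0.0
        )
        blk = expr.values[np.ix_(rl == 0, cl == 0)]
        assert blk.std() == 0.0
        assert blk.flat[0] == pytest.approx(5.0)

    def test_labels_cover_all_groups(self):
        _, rl, cl = make_checkerboard(30, 20, 4, 3, seed=5)
        assert set(rl) == set(range(4))
        assert set(cl) == set(range(3))


class TestInjectNoisyGenes:
    def test_zero_noisy_is_identity(self, small_expr):
        out, ids = inject_noisy_genes(small_expr, np.arange(10.0), 0, seed=0)
        np.testing.assert_array_equal(out.values, small_expr.values)
        assert ids == []

    def test_lowest_weight_genes_replaced_within_range(self, small_expr):
        w = np.arange(10.0)  # genes g0, g1, g2 have the lowest weights
        out, ids = inject_noisy_genes(small_expr, w, 3, seed=0)
        assert ids == ["g0", "g1", "g2"]
        lo, hi = small_expr.values.min(), small_expr.values.max()
        assert (out.values[:3] >= lo).all() and (out.values[:3] <= hi).all()
        np.testing.assert_array_equal(out.values[3:], small_expr.values[3:])


class TestPerturbNetwork:
    def make_net(self, seed=0):
        return generate_structured_network(20, range(8), 0.4, 0.1, seed=seed)

    def test_no_op(self):
        net = self.make_net()
        out = perturb_network(net, seed=1)
        np.testing.assert_array_equal(
            out.adjacency.toarray(), net.adjacency.toarray()
        )

    def test_edge_count_bookkeeping(self):
        net = self.make_net()
        out = perturb_network(net, n_add=3, n_delete=2, n_rewire=5, seed=1)
        assert out.n_edges == net.n_edges + 3 - 2

    @pytest.mark.parametrize("seed", range(5))
    def test_no_self_loops_or_duplicates_or_asymmetry(self, seed):
        net = self.make_net(seed)
        out = perturb_network(net, n_add=4, n_delete=4, n_rewire=10, seed=seed)
        A = out.adjacency.toarray()
        assert np.diag(A).sum() == 0
        assert set(np.unique(A)) <= {0.0, 1.0}
        np.testing.assert_array_equal(A, A.T)

    def test_insufficient_supply_raises(self):
        net = self.make_net()
        with pytest.raises(ValueError, match="deletable"):
            perturb_network(net, n_delete=10**6, seed=0)


class TestStructuredNetwork:
    def test_hub_star(self):
        net = generate_structured_network(3, [0], p_hub=1.0, p_background=0.0, seed=0)
        A = net.adjacency.toarray()
        assert A[0, 1] == A[0, 2] == 1
        assert A[1, 2] == 0

    def test_informative_degree_exceeds_background(self):
        net = generate_structured_network(
            200, range(50), p_hub=0.2, p_background=0.01, seed=4
        )
        deg = net.degrees
        assert deg[:50].mean() > deg[50:].mean()

    def test_equal_probabilities_are_erdos_renyi(self):
        net = generate_structured_network(200, range(50), 0.1, 0.1, seed=6)
        deg = net.degrees
        # no degree advantage for the "informative" set
        assert abs(deg[:50].mean() - deg[50:].mean()) < 3.0
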