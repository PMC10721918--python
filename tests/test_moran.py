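"""Global and local Moran's I: oracle equivalence, closed forms, identities
and permutation behaviour."""

import numpy as np
import pytest

from pollugrid.grid import GridSpec
from pollugrid.moran import (build_contiguity_weights, classify_clusters,
                             global_morans_i, local_morans_i)


def brute_force_moran(x, W_dense):
    """Textbook double sum, O(n^2)."""
    x = np.asarray(x, float)
    z = x - x.mean()
    n = len(x)
    S0 = W_dense.sum()
    num = sum(W_dense[i, j] * z[i] * z[j]
              for i in range(n) for j in range(n))
    return n / S0 * num / (z @ z)


def grid(nr, nc):
    return GridSpec(x0=0, y0=0, cell_size=100, n_rows=nr, n_cols=nc)


class TestWeights:
    def test_queen_neighbour_counts_3x3(self):
        w = build_contiguity_weights(grid(3, 3), "queen", "binary")
        deg = np.asarray(w.W.sum(axis=1)).ravel()
        assert deg[4] == 8                      # center
        assert deg[0] == deg[2] == deg[6] == deg[8] == 3

    def test_rook_neighbour_counts_3x3(self):
        w = build_contiguity_weights(grid(3, 3), "rook", "binary")
        deg = np.asarray(w.W.sum(axis=1)).ravel()
        assert deg[4] == 4
        assert deg[0] == 2

    def test_row_standardized_rows_sum_to_one(self):
        w = build_contiguity_weights(grid(5, 7), "queen", "row")
        rows = np.asarray(w.W.sum(axis=1)).ravel()
        np.testing.assert_allclose(rows, 1.0, atol=1e-12)
        assert w.scheme == "queen" and len(w.islands) == 0

    def test_symmetric_before_standardization(self):
        w = build_contiguity_weights(grid(4, 4), "queen", "binary")
        assert (w.W != w.W.T).nnz == 0
        assert w.W.diagonal().sum() == 0        # no self-neighbours

    def test_single_cell_grid_rejected(self):
        with pytest.raises(ValueError, match="two cells"):
            build_contiguity_weights(grid(1, 1))


class TestGlobalMoran:
    def test_checkerboard_on_rook_is_minus_one(self):
        """Row-standardized rook lag of a checkerboard equals the negated
        value at every cell, so I = -1 exactly."""
        spec = grid(8, 8)
        w = build_contiguity_weights(spec, "rook", "row")
        r, c = np.divmod(np.arange(64), 8)
        x = ((r + c) % 2).astype(float)
        res = global_morans_i(x, w, n_permutations=0)
        assert res.I == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_on_random_fields(self, rng):
        spec = grid(8, 8)
        w = build_contiguity_weights(spec, "queen", "row")
        W_dense = w.W.toarray()
        for _ in range(100):
            x = rng.normal(size=64)
            res = global_morans_i(x, w, n_permutations=0)
            assert abs(res.I - brute_force_moran(x, W_dense)) < 1e-12

    def test_smooth_gradient_positively_autocorrelated(self):
        spec = grid(10, 10)
        w = build_contiguity_weights(spec, "queen", "row")
        cen = spec.centroids()
        x = cen[:, 0] + cen[:, 1]
        res = global_morans_i(x, w, n_permutations=199, seed=0)
        assert res.I > 0 and res.p_value < 0.05

    def test_constant_field_rejected(self):
        w = build_contiguity_weights(grid(3, 3))
        with pytest.raises(ValueError, match="constant"):
            global_morans_i(np.ones(9), w)

    def test_permutation_mean_near_expectation(self, rng):
        """Permuting an exchangeable field, E[I] = -1/(n-1); the empirical
        permutation mean should sit within 3 standard errors."""
        spec = grid(6, 6)
        w = build_contiguity_weights(spec, "queen", "row")
        z = rng.normal(size=36)
        z = z - z.mean()
        nperm = 9999
        g = np.random.default_rng(7)
        perms = g.permuted(np.tile(z, (nperm, 1)), axis=1)
        lags = perms @ w.W.T.toarray()
        I_sim = 36 / w.S0 * (perms * lags).sum(axis=1) / (z @ z)
        se = I_sim.std() / np.sqrt(nperm)
        assert abs(I_sim.mean() - (-1 / 35)) < 3 * se


class TestLocalMoran:
    def test_sum_identity_with_global(self, rng):
        spec = grid(8, 8)
        w = build_contiguity_weights(spec, "queen", "row")
        for _ in range(10):
            x = rng.normal(size=64)
            res = local_morans_i(x, w, n_permutations=0)
            assert abs(res.I.sum() - 64 * res.global_I) < 1e-10

    def test_spatial_outlier_is_high_low(self):
        spec = grid(3, 3)
        w = build_contiguity_weights(spec, "queen", "row")
        x = np.zeros(9)
        x[4] = 10.0
        res = local_morans_i(x, w, n_permutations=0)
        assert res.quadrant[4] == "HL"

    def test_determinism_and_seed_independence_of_statistic(self, rng):
        spec = grid(6, 6)
        w = build_contiguity_weights(spec, "queen", "row")
        x = rng.normal(size=36)
        r1 = local_morans_i(x, w, n_permutations=99, seed=1)
        r2 = local_morans_i(x, w, n_permutations=99, seed=1)
        r3 = local_morans_i(x, w, n_permutations=99, seed=2)
        np.testing.assert_array_equal(r1.p_value, r2.p_value)
        np.testing.assert_array_equal(r1.I, r3.I)   # statistic seed-free

    def test_positive_scaling_changes_nothing(self, rng):
        spec = grid(6, 6)
        w = build_contiguity_weights(spec, "queen", "row")
        x = rng.normal(size=36)
        a = local_morans_i(x, w, n_permutations=99, seed=3)
        b = local_morans_i(5.0 * x, w, n_permutations=99, seed=3)
        np.testing.assert_allclose(a.I, b.I, atol=1e-12)
        np.testing.assert_array_equal(a.quadrant, b.quadrant)
        np.testing.assert_array_equal(classify_clusters(a),
                                      classify_clusters(b))


class TestClassify:
    @pytest.fixture
    def two_block_result(self):
        spec = grid(12, 12)
        w = build_contiguity_weights(spec, "queen", "row")
        rng = np.random.default_rng(5)
        r, _ = np.divmod(np.arange(144), 12)
        x = np.where(r < 6, 10.0, 0.0) + rng.normal(0, 0.5, 144)
        return local_morans_i(x, w, n_permutations=999, seed=5)

    def test_alpha_one_labels_every_cell_by_quadrant(self, two_block_result):
        labels = classify_clusters(two_block_result, alpha=1.0)
        assert set(labels) <= {"HH", "LL", "HL", "LH"}

    def test_tiny_alpha_labels_nothing(self, two_block_result):
        labels = classify_clusters(two_block_result, alpha=1e-9)
        assert set(labels) == {"not-significant"}

    def test_two_block_field_finds_hh_and_ll(self, two_block_result):
        labels = classify_clusters(two_block_result, alpha=0.05)
        assert "HH" in labels and "LL" in labels

    def test_invalid_alpha_rejected(self, two_block_result):
        with pytest.raises(ValueError, match="alpha"):
            classify_clusters(two_block_result, alpha=0.0)
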