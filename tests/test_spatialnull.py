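"""Moran spectral randomization: weights, eigenbasis, surrogates, test."""

import numpy as np
import pytest

from tremornet import errors
from tremornet.spatialnull import (
    build_weights,
    moran_eigenbasis,
    morans_i,
    msr_surrogates,
    naive_shuffle_test,
    similarity_test,
    similarity_test_both_directions,
)
from tremornet.volumes import BrainMap, VolumeGrid
from tests.conftest import smooth_field


def flat_grid(n1, n2, voxel=1.0):
    return VolumeGrid((n1, n2, 1), (voxel, voxel, voxel))


class TestWeights:
    def test_inverse_squared_distance_for_neighbors_two_mm_apart(self):
        g = VolumeGrid((3, 1, 1), (2.0, 2.0, 2.0))
        w = build_weights(g, np.ones(g.shape, dtype=bool), power=2)
        assert w.weights[0, 1] == pytest.approx(1.0 / 4.0)

    def test_collinear_voxels_weight_values(self):
        g = VolumeGrid((3, 1, 1), (3.0, 3.0, 3.0))
        w = build_weights(g, np.ones(g.shape, dtype=bool), power=2)
        assert w.weights[0, 1] == pytest.approx(1.0 / 9.0)
        assert w.weights[1, 2] == pytest.approx(1.0 / 9.0)
        assert w.weights[0, 2] == pytest.approx(1.0 / 36.0)
        assert np.all(np.diag(w.weights) == 0)

    def test_coordinate_scaling_scales_weights_and_leaves_i_invariant(self, rng):
        g1 = flat_grid(4, 4, voxel=1.0)
        g2 = flat_grid(4, 4, voxel=3.0)
        mask = np.ones(g1.shape, dtype=bool)
        w1 = build_weights(g1, mask)
        w2 = build_weights(g2, mask)
        np.testing.assert_allclose(w2.weights, w1.weights / 9.0)
        x = rng.normal(size=16)
        assert morans_i(x, w1) == pytest.approx(morans_i(x, w2))

    def test_voxel_cap_enforced(self):
        g = flat_grid(5, 5)
        with pytest.raises(errors.ResourceCapError):
            build_weights(g, np.ones(g.shape, dtype=bool), voxel_cap=10)


class TestMoransI:
    def test_permutation_null_mean_matches_theory(self, rng):
        g = flat_grid(4, 4)
        w = build_weights(g, np.ones(g.shape, dtype=bool))
        x = rng.normal(size=16)
        draws = [morans_i(rng.permutation(x), w) for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(-1.0 / 15.0, abs=0.01)

    def test_smooth_gradient_is_positively_autocorrelated(self):
        g = flat_grid(3, 3)
        w = build_weights(g, np.ones(g.shape, dtype=bool))
        gradient = g.world_coords()[:, 0]  # monotone in x
        # brute-force the standard formula as an independent oracle
        z = gradient - gradient.mean()
        oracle = (
            w.n / w.weights.sum() * (z @ w.weights @ z) / (z @ z)
        )
        assert morans_i(gradient, w) == pytest.approx(oracle)
        assert morans_i(gradient, w) > 0

    def test_constant_map_rejected(self):
        g = flat_grid(3, 3)
        w = build_weights(g, np.ones(g.shape, dtype=bool))
        with pytest.raises(errors.UndefinedStatisticError):
            morans_i(np.ones(9), w)


class TestEigenbasis:
    def test_orthonormal_centered_and_mem_identity(self):
        g = flat_grid(4, 4)
        w = build_weights(g, np.ones(g.shape, dtype=bool))
        basis = moran_eigenbasis(w)
        gram = basis.eigenvectors.T @ basis.eigenvectors
        np.testing.assert_allclose(gram, np.eye(15), atol=1e-8)
        np.testing.assert_allclose(basis.eigenvectors.sum(axis=0), 0.0, atol=1e-8)
        for k in (0, 7, 14):
            expected = basis.n / basis.s0 * basis.eigenvalues[k]
            assert morans_i(basis.eigenvectors[:, k], w) == pytest.approx(
                expected, abs=1e-6
            )


class TestSurrogates:
    def test_moments_and_moran_spectrum_preserved(self, tiny_grid, tiny_mask, tiny_basis, rng):
        weights, basis = tiny_basis
        x = smooth_field(tiny_grid, tiny_mask, rng).values
        surr = msr_surrogates(x, basis, 50, seed=1)
        np.testing.assert_allclose(surr.mean(axis=1), x.mean(), atol=1e-10)
        np.testing.assert_allclose(surr.var(axis=1), x.var(), atol=1e-10)
        i_obs = morans_i(x, weights)
        i_surr = np.mean([morans_i(s, weights) for s in surr])
        assert abs(i_surr - i_obs) <= max(0.1 * abs(i_obs), 0.01)

    def test_same_seed_reproduces_ensemble(self, tiny_basis, tiny_grid, tiny_mask, rng):
        _, basis = tiny_basis
        x = smooth_field(tiny_grid, tiny_mask, rng).values
        s1 = msr_surrogates(x, basis, 10, seed=7)
        s2 = msr_surrogates(x, basis, 10, seed=7)
        np.testing.assert_array_equal(s1, s2)

    def test_invalid_surrogate_count_rejected(self, tiny_basis, tiny_grid, tiny_mask, rng):
        _, basis = tiny_basis
        x = smooth_field(tiny_grid, tiny_mask, rng).values
        with pytest.raises(errors.ConfigError):
            msr_surrogates(x, basis, 0)


class TestSimilarityTest:
    def test_identical_maps_give_rho_one(self, tiny_grid, tiny_mask, tiny_basis, rng):
        _, basis = tiny_basis
        a = smooth_field(tiny_grid, tiny_mask, rng)
        res = similarity_test(a, a, n_surr=50, seed=0, basis=basis)
        assert res.rho_obs == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self, tiny_grid, tiny_mask, tiny_basis, rng):
        _, basis = tiny_basis
        a = smooth_field(tiny_grid, tiny_mask, rng)
        b = a.with_values(np.exp(2.0 * a.values) + 5.0)
        res = similarity_test(a, b, n_surr=50, seed=0, basis=basis)
        assert res.rho_obs == pytest.approx(1.0)
        # the whole test (not just rho) is invariant to monotone transforms
        # of the non-permuted map, whose values enter only through ranks
        c = smooth_field(tiny_grid, tiny_mask, rng)
        r1 = similarity_test(a, c, n_surr=100, seed=3, basis=basis, permuted_side="a")
        r2 = similarity_test(
            a, c.with_values(np.tanh(c.values)), n_surr=100, seed=3,
            basis=basis, permuted_side="a",
        )
        assert r1.rho_obs == pytest.approx(r2.rho_obs)
        assert r1.p == pytest.approx(r2.p)

    def test_both_directions_share_rho_but_not_null(self, tiny_grid, tiny_mask, rng):
        a = smooth_field(tiny_grid, tiny_mask, rng)
        b = smooth_field(tiny_grid, tiny_mask, rng)
        ra, rb = similarity_test_both_directions(a, b, n_surr=100, seed=5)
        assert ra.rho_obs == pytest.approx(rb.rho_obs)
        assert ra.permuted_side == "a" and rb.permuted_side == "b"

    def test_zero_exceedances_reported_as_upper_bound(self, tiny_grid, tiny_mask, tiny_basis, rng):
        _, basis = tiny_basis
        a = smooth_field(tiny_grid, tiny_mask, rng)
        res = similarity_test(a, a, n_surr=50, seed=1, basis=basis)
        assert res.p == pytest.approx(1.0 / 50)
        assert res.p_is_upper_bound

    def test_constant_support_rejected(self, tiny_grid, tiny_mask, tiny_basis, rng):
        _, basis = tiny_basis
        a = smooth_field(tiny_grid, tiny_mask, rng)
        const = a.with_values(np.full(a.n_voxels, 2.0))
        with pytest.raises(errors.UndefinedStatisticError):
            similarity_test(a, const, n_surr=10, seed=0, basis=basis)

    def test_naive_shuffle_agrees_on_rho(self, tiny_grid, tiny_mask, rng):
        a = smooth_field(tiny_grid, tiny_mask, rng)
        b = smooth_field(tiny_grid, tiny_mask, rng)
        msr = similarity_test(a, b, n_surr=20, seed=0)
        naive = naive_shuffle_test(a, b, n_perm=20, seed=0)
        assert naive.rho_obs == pytest.approx(msr.rho_obs)
        assert naive.procedure == "iid_shuffle"
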