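import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gsdir.blending import (
    BlendConfig,
    blend_backward,
    blend_displacements,
    blend_forward,
    blend_weights,
    knn,
    local_transform,
)
from gsdir.core_model import GaussianPrimitiveSet, init_grid_primitives

from oracles import naive_blend_point, naive_knn, random_prims


def _iso_pair():
    """Two congruent isotropic unit-scale primitives on the x axis."""
    return GaussianPrimitiveSet(
        mu=np.array([[-0.5, 0, 0], [0.5, 0, 0]]),
        log_s=np.zeros((2, 3)),
        q=np.tile([1.0, 0, 0, 0], (2, 1)),
        r=np.tile([1.0, 0, 0, 0], (2, 1)),
        t=np.zeros((2, 3)),
        scale_id=[0, 0],
    )


class TestKnn:
    def test_all_returned_when_k_equals_count(self, rng):
        prims = random_prims(rng, 7)
        idx = knn(prims, np.zeros((1, 3)), K=7, scale=0)
        assert sorted(idx[0]) == list(range(7))

    def test_query_at_centre_returns_that_primitive(self, rng):
        prims = random_prims(rng, 12)
        for i in (0, 5, 11):
            assert knn(prims, prims.mu[i][None], K=1, scale=0)[0, 0] == i

    def test_matches_exhaustive_sort(self, rng):
        prims = random_prims(rng, 50)
        queries = rng.uniform(-1, 1, (20, 3))
        got = knn(prims, queries, K=5, scale=0)
        for j, pt in enumerate(queries):
            assert set(got[j]) == set(naive_knn(prims.mu, pt, 5))

    def test_k_too_large_errors(self, rng):
        prims = random_prims(rng, 4)
        with pytest.raises(ValueError):
            knn(prims, np.zeros((1, 3)), K=5, scale=0)

    def test_restricted_to_requested_scale(self, rng):
        prims = random_prims(rng, 20, n_scales=2)
        idx = knn(prims, rng.uniform(-1, 1, (15, 3)), K=3, scale=1)
        assert np.all(prims.scale_id[idx] == 1)


class TestWeights:
    def test_k1_weight_is_one(self, rng):
        prims = random_prims(rng, 5)
        pts = rng.uniform(-2, 2, (8, 3))
        nbr = knn(prims, pts, K=1, scale=0)
        w, _ = blend_weights(prims, pts, nbr)
        assert np.allclose(w, 1.0)

    def test_equidistant_congruent_pair_splits_evenly(self):
        prims = _iso_pair()
        w, _ = blend_weights(prims, np.array([[0.0, 0.3, -0.2]]), np.array([[0, 1]]))
        assert np.allclose(w, [0.5, 0.5], atol=1e-12)

    def test_mahalanobis_ratio_case(self):
        # unit-scale isotropic kernels at Mahalanobis distances 1 and 2:
        # normalizers cancel, w1 = e^-0.5 / (e^-0.5 + e^-2)
        prims = GaussianPrimitiveSet(
            mu=np.array([[1.0, 0, 0], [0, 2.0, 0]]),
            log_s=np.zeros((2, 3)),
            q=np.tile([1.0, 0, 0, 0], (2, 1)),
            r=np.tile([1.0, 0, 0, 0], (2, 1)),
            t=np.zeros((2, 3)),
            scale_id=[0, 0],
        )
        w, _ = blend_weights(prims, np.zeros((1, 3)), np.array([[0, 1]]))
        expect = np.exp(-0.5) / (np.exp(-0.5) + np.exp(-2.0))
        assert w[0, 0] == pytest.approx(expect, abs=1e-9)

    def test_raw_weights_are_full_densities(self):
        # at the centre of a unit isotropic kernel the density is (2 pi)^-3/2
        prims = _iso_pair()
        _, raw = blend_weights(prims, prims.mu[[0]], np.array([[0, 1]]))
        assert raw[0, 0] == pytest.approx((2 * np.pi) ** -1.5, rel=1e-12)

    def test_distant_point_falls_back_to_uniform(self):
        prims = _iso_pair()
        prims.log_s[:] = np.log(1e-3)  # tiny kernels: densities underflow far away
        w, _ = blend_weights(prims, np.array([[50.0, 50.0, 50.0]]), np.array([[0, 1]]))
        assert np.all(np.isfinite(w))
        assert np.allclose(w.sum(), 1.0, atol=1e-6)


class TestLocalTransform:
    def test_identity(self, rng):
        prims = init_grid_primitives([(2, 2, 2)])
        pts = rng.uniform(-1, 1, (5, 3))
        assert np.allclose(local_transform(prims, 0, pts), pts)

    def test_pure_translation(self, rng):
        prims = init_grid_primitives([(2, 2, 2)])
        prims.t[3] = [0.1, 0, 0]
        pts = rng.uniform(-1, 1, (5, 3))
        assert np.allclose(local_transform(prims, 3, pts), pts + [0.1, 0, 0])

    def test_rotation_about_own_centre(self):
        prims = init_grid_primitives([(2, 2, 2)])
        prims.mu[0] = 0.0
        prims.r[0] = [np.cos(np.pi / 4), 0, 0, np.sin(np.pi / 4)]  # 90 deg about z
        out = local_transform(prims, 0, np.array([[0.5, 0.0, 0.0]]))
        assert np.allclose(out, [[0.0, 0.5, 0.0]], atol=1e-12)


class TestBlendDisplacements:
    def test_identity_primitives_give_zero(self, rng):
        prims = init_grid_primitives([(4, 4, 4)])
        res = blend_displacements(prims, rng.uniform(-1, 1, (50, 3)), BlendConfig(K=8))
        assert np.all(res.displacement == 0.0)

    def test_shared_translation_partition_of_unity(self, rng):
        prims = init_grid_primitives([(4, 4, 4)])
        prims.t[:] = [0.2, 0.0, 0.0]
        res = blend_displacements(prims, rng.uniform(-1, 1, (50, 3)), BlendConfig(K=8))
        assert np.allclose(res.displacement, [0.2, 0.0, 0.0], atol=1e-9)

    def test_matches_naive_two_primitives(self, rng):
        prims = random_prims(rng, 2)
        pts = rng.uniform(-1, 1, (10, 3))
        res = blend_displacements(prims, pts, BlendConfig(K=2))
        for j in range(10):
            assert np.allclose(
                res.displacement[j], naive_blend_point(prims, pts[j], 2), atol=1e-10
            )

    @given(st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_naive_random_configs(self, seed):
        r = np.random.default_rng(seed)
        n_scales = int(r.integers(1, 3))
        prims = random_prims(r, int(r.integers(6, 16)) * n_scales, n_scales=n_scales)
        K = int(r.integers(1, 6))
        pts = r.uniform(-1.2, 1.2, (4, 3))
        res = blend_displacements(prims, pts, BlendConfig(K=K))
        for j in range(4):
            assert np.allclose(
                res.displacement[j], naive_blend_point(prims, pts[j], K), atol=1e-5
            )

    def test_translation_equivariance(self, rng):
        prims = random_prims(rng, 16, n_scales=2)
        pts = rng.uniform(-1, 1, (30, 3))
        base = blend_displacements(prims, pts, BlendConfig(K=4)).displacement
        shifted = prims.copy()
        shifted.t += [0.05, -0.03, 0.02]
        out = blend_displacements(shifted, pts, BlendConfig(K=4)).displacement
        assert np.allclose(out, base + [0.05, -0.03, 0.02], atol=1e-9)

    def test_locality_of_far_primitive(self, rng):
        # a primitive outside every K-neighbourhood can move anywhere without
        # changing a single bit of the field
        prims = random_prims(rng, 12)
        prims.mu[7] = [40.0, 40.0, 40.0]
        pts = rng.uniform(-0.5, 0.5, (20, 3))
        assert 7 not in knn(prims, pts, 4, 0)
        base = blend_displacements(prims, pts, BlendConfig(K=4)).displacement
        far = prims.copy()
        far.mu[7] = [80.0, -80.0, 80.0]
        far.t[7] = [5.0, 5.0, 5.0]
        assert 7 not in knn(far, pts, 4, 0)
        out = blend_displacements(far, pts, BlendConfig(K=4)).displacement
        assert np.array_equal(out, base)

    def test_partition_of_unity_random_sets(self, rng):
        prims = random_prims(rng, 24, n_scales=2)
        pts = rng.uniform(-1, 1, (500, 3))
        res = blend_displacements(prims, pts, BlendConfig(K=6))
        for w in res.weights.values():
            assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)
            assert np.all((w >= 0) & (w <= 1.0 + 1e-12))

    def test_neighbor_indices_distinct(self, rng):
        prims = random_prims(rng, 20)
        res = blend_displacements(prims, rng.uniform(-1, 1, (40, 3)), BlendConfig(K=5))
        nbr = res.neighbor_idx[0]
        assert all(len(set(row)) == 5 for row in nbr)


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        prims = random_prims(rng, 12, n_scales=2)
        pts = rng.uniform(-1, 1, (7, 3))
        cfg = BlendConfig(K=4)
        g_phi = rng.standard_normal((7, 3))
        _, caches = blend_forward(prims, pts, cfg)
        grads = blend_backward(prims, caches, g_phi)

        def loss(p):
            res, _ = blend_forward(p, pts, cfg)
            return float((g_phi * res.displacement).sum())

        eps = 1e-6
        for block in ("mu", "log_s", "q", "r", "t"):
            arr = getattr(prims, block)
            fd = np.zeros_like(arr)
            for i in range(arr.shape[0]):
                for j in range(arr.shape[1]):
                    p2, p3 = prims.copy(), prims.copy()
                    getattr(p2, block)[i, j] += eps
                    getattr(p3, block)[i, j] -= eps
                    fd[i, j] = (loss(p2) - loss(p3)) / (2 * eps)
            scale = max(1.0, np.abs(fd).max())
            assert np.abs(fd - grads[block]).max() / scale < 1e-5, block
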