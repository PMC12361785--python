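import numpy as np
import pytest

from gsdir.objective import (
    LossConfig,
    ncc_loss,
    ncc_loss_grad,
    sample_batch,
    total_loss,
    tv_loss,
    tv_loss_grad,
)


class TestSampleBatch:
    def test_default_batch_partition_counts(self):
        cfg = LossConfig(batch_size=20_000)
        batch = sample_batch((40, 40, 40), cfg, np.random.default_rng(0))
        assert batch.sim_voxels.shape == (20_000, 3)
        assert batch.tv_seeds.shape == (5_000, 3)
        assert batch.tv_neighbors.shape == (5_000, 3, 3)

    def test_deterministic_under_seed(self):
        cfg = LossConfig(batch_size=512)
        b1 = sample_batch((16, 16, 16), cfg, np.random.default_rng(42))
        b2 = sample_batch((16, 16, 16), cfg, np.random.default_rng(42))
        assert np.array_equal(b1.sim_voxels, b2.sim_voxels)
        assert np.array_equal(b1.tv_seeds, b2.tv_seeds)

    def test_all_indices_in_bounds_exhaustive(self):
        shape = (4, 4, 4)
        cfg = LossConfig(batch_size=16)
        batch = sample_batch(shape, cfg, np.random.default_rng(7))
        for arr in (batch.sim_voxels, batch.tv_seeds, batch.tv_neighbors.reshape(-1, 3)):
            assert np.all(arr >= 0)
            assert np.all(arr < shape)

    def test_neighbors_are_forward_unit_steps(self):
        cfg = LossConfig(batch_size=100)
        batch = sample_batch((10, 12, 14), cfg, np.random.default_rng(3))
        assert np.array_equal(
            batch.tv_neighbors - batch.tv_seeds[:, None, :],
            np.tile(np.eye(3, dtype=int), (batch.tv_seeds.shape[0], 1, 1)),
        )

    def test_oversized_batch_falls_back_to_replacement(self):
        cfg = LossConfig(batch_size=1000)
        batch = sample_batch((4, 4, 4), cfg, np.random.default_rng(0))
        assert batch.sim_voxels.shape == (1000, 3)


class TestNcc:
    def test_identical_is_minus_one(self, rng):
        x = rng.standard_normal(100)
        assert ncc_loss(x, x) == pytest.approx(-1.0, abs=1e-12)

    def test_negated_is_plus_one(self, rng):
        x = rng.standard_normal(100)
        assert ncc_loss(-x, x) == pytest.approx(1.0, abs=1e-12)

    def test_hand_pearson_case(self):
        # corr((1,2,3,4),(1,2,3,5)) = 6.5 / (sqrt(5) * sqrt(8.75))
        expect = 6.5 / (np.sqrt(5.0) * np.sqrt(8.75))
        assert expect == pytest.approx(0.982708, abs=5e-7)
        assert ncc_loss([1, 2, 3, 4], [1, 2, 3, 5]) == pytest.approx(-expect, abs=1e-12)

    def test_affine_intensity_invariance(self, rng):
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        base = ncc_loss(x, y)
        assert ncc_loss(3.2 * x + 11.0, y) == pytest.approx(base, abs=1e-6)
        assert ncc_loss(x, 0.7 * y - 4.0) == pytest.approx(base, abs=1e-6)

    def test_zero_variance_returns_zero(self):
        assert ncc_loss(np.ones(10), np.arange(10.0)) == 0.0

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            ncc_loss([1.0, np.nan, 2.0], [1.0, 2.0, 3.0])

    def test_gradient_matches_finite_differences(self, rng):
        w = rng.standard_normal(30)
        f = rng.standard_normal(30)
        _, g = ncc_loss_grad(w, f)
        eps = 1e-7
        for i in range(30):
            wp, wm = w.copy(), w.copy()
            wp[i] += eps
            wm[i] -= eps
            fd = (ncc_loss(wp, f) - ncc_loss(wm, f)) / (2 * eps)
            assert g[i] == pytest.approx(fd, abs=1e-6)


class TestTv:
    @staticmethod
    def _field_fn(phi):
        def dvf_at(idx):
            idx = np.asarray(idx, dtype=int)
            return phi[idx[:, 0], idx[:, 1], idx[:, 2]]

        return dvf_at

    def test_constant_and_zero_fields_give_zero(self):
        cfg = LossConfig(batch_size=64)
        batch = sample_batch((8, 8, 8), cfg, np.random.default_rng(0))
        zero = np.zeros((8, 8, 8, 3))
        const = np.full((8, 8, 8, 3), 0.37)
        assert tv_loss(self._field_fn(zero), batch) == 0.0
        assert tv_loss(self._field_fn(const), batch) == pytest.approx(0.0, abs=1e-12)

    def test_linear_field_closed_form(self):
        # phi_x = a * x_canonical: forward diff along axis 0 is a*h, others 0
        n = 9
        a = 0.3
        h = 2.0 / (n - 1)
        x_c = np.linspace(-1, 1, n)
        phi = np.zeros((n, n, n, 3))
        phi[..., 0] = x_c[:, None, None] * a
        cfg = LossConfig(batch_size=40)
        batch = sample_batch((n, n, n), cfg, np.random.default_rng(5))
        assert tv_loss(self._field_fn(phi), batch) == pytest.approx(a * h, abs=1e-12)

    def test_zero_iff_sampled_differences_zero(self, rng):
        n = 8
        phi = rng.standard_normal((n, n, n, 3)) * 0.01
        cfg = LossConfig(batch_size=40)
        batch = sample_batch((n, n, n), cfg, np.random.default_rng(2))
        assert tv_loss(self._field_fn(phi), batch) > 0.0

    def test_unbiased_estimate_of_full_grid_tv(self):
        # batch TV averaged over seeded batches matches the full-grid mean
        n = 16
        r = np.random.default_rng(11)
        from scipy.ndimage import gaussian_filter

        phi = np.stack(
            [gaussian_filter(r.standard_normal((n, n, n)), 3.0) for _ in range(3)],
            axis=-1,
        ) * 0.05
        fn = self._field_fn(phi)
        seeds = np.stack(
            np.meshgrid(*[np.arange(n - 1)] * 3, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        full = 0.0
        for d in range(3):
            e = np.zeros(3, dtype=int)
            e[d] = 1
            full += np.abs(fn(seeds + e) - fn(seeds)).sum(1)
        full_mean = full.mean()
        cfg = LossConfig(batch_size=256)
        vals = np.array(
            [tv_loss(fn, sample_batch((n, n, n), cfg, np.random.default_rng(500 + i)))
             for i in range(100)]
        )
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - full_mean) < 3 * se

    def test_gradient_matches_finite_differences(self, rng):
        S = 6
        seed = rng.standard_normal((S, 3)) * 0.1
        nbr = rng.standard_normal((S, 3, 3)) * 0.1
        for norm in ("l1", "l2"):
            val, g_seed, g_nbr = tv_loss_grad(seed, nbr, norm)
            eps = 1e-7

            def f(sd, nb):
                diff = nb - sd[:, None, :]
                if norm == "l1":
                    return np.abs(diff).sum(axis=(1, 2)).mean()
                return np.linalg.norm(diff, axis=2).sum(axis=1).mean()

            assert val == pytest.approx(f(seed, nbr), abs=1e-12)
            for i in range(S):
                for j in range(3):
                    sp, sm = seed.copy(), seed.copy()
                    sp[i, j] += eps
                    sm[i, j] -= eps
                    assert g_seed[i, j] == pytest.approx(
                        (f(sp, nbr) - f(sm, nbr)) / (2 * eps), abs=1e-6
                    )


class TestTotalLoss:
    def test_weighted_sum(self):
        cfg = LossConfig(lambda_reg=8.0)
        assert total_loss(-0.9, 0.01, cfg) == pytest.approx(-0.82, abs=1e-12)

    def test_lambda_zero_is_similarity_only(self):
        cfg = LossConfig(lambda_reg=0.0)
        assert total_loss(-0.77, 123.0, cfg) == -0.77

    def test_default_lambda_is_eight(self):
        assert LossConfig().lambda_reg == 8.0
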