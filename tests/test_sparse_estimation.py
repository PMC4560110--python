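"""Unit and property tests for adaptive-thresholding sparse estimation."""

import numpy as np
import pytest

from dynconn import (
    DataValidationError,
    SparsityMask,
    TimeSeriesMatrix,
    element_variance,
    empirical_moments,
    estimate_sparse_params,
    jackknife_element_variance,
    threshold_covariance,
    threshold_mean,
)
from dynconn.sparse_estimation import _element_variances


class TestEmpiricalMoments:
    def test_two_point_hand_computation(self):
        mean, cov = empirical_moments([[0, 0], [2, 2]])
        np.testing.assert_allclose(mean, [1.0, 1.0])
        np.testing.assert_allclose(cov, [[1.0, 1.0], [1.0, 1.0]])

    def test_constant_series_zero_covariance(self):
        mean, cov = empirical_moments(np.full((7, 3), 4.2))
        np.testing.assert_allclose(mean, [4.2] * 3)
        np.testing.assert_array_equal(cov, np.zeros((3, 3)))

    def test_white_noise_off_diagonals_vanish(self, rng):
        t = 100_000
        y = rng.standard_normal((t, 3))
        _, cov = empirical_moments(y)
        off = cov[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 3 / np.sqrt(t))

    def test_ml_divisor_is_t(self, rng):
        y = rng.standard_normal((10, 2))
        _, cov = empirical_moments(y)
        np.testing.assert_allclose(cov, np.cov(y.T, ddof=0), atol=1e-12)

    def test_rejects_nonfinite(self):
        with pytest.raises(DataValidationError, match="non-finite"):
            empirical_moments([[0.0, np.nan], [1.0, 2.0]])

    def test_rejects_single_row(self):
        with pytest.raises(DataValidationError):
            empirical_moments([[1.0, 2.0]])


class TestElementVariance:
    def test_hand_computation(self):
        y = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
        # X = (1, 1, -1, -1), Xbar = 0 -> delta^2 = 1
        assert element_variance(y, np.zeros(2), 0, 1) == pytest.approx(1.0)

    def test_constant_channel_degenerate(self):
        y = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        assert element_variance(y, y.mean(axis=0), 0, 1) == 0.0

    def test_diagonal_tends_to_chi2_variance(self, rng):
        # Var[(y - mu)^2] = 2 for standard normal data
        y = rng.standard_normal((200_000, 1))
        d2 = element_variance(y, np.zeros(1), 0, 0)
        assert d2 == pytest.approx(2.0, rel=0.05)

    def test_vectorised_matches_scalar(self, rng):
        y = rng.standard_normal((50, 4))
        mean = y.mean(axis=0)
        full = _element_variances(y, mean)
        for i in range(4):
            for j in range(4):
                assert full[i, j] == pytest.approx(element_variance(y, mean, i, j))


class TestJackknife:
    def test_agrees_with_clt_variance(self, rng):
        t = 2000
        y = rng.standard_normal((t, 2))
        jack = jackknife_element_variance(y, 0, 1)
        clt = element_variance(y, y.mean(axis=0), 0, 1) / t
        assert jack == pytest.approx(clt, rel=0.1)

    def test_constant_channel_is_zero(self):
        y = np.column_stack([np.full(10, 2.0), np.arange(10.0)])
        assert jackknife_element_variance(y, 0, 1) == pytest.approx(0.0, abs=1e-15)

    def test_t3_matches_direct_enumeration(self):
        y = np.array([[1.0, 2.0], [3.0, -1.0], [0.0, 4.0]])

        def cov01(sub):
            c = sub - sub.mean(axis=0)
            return (c[:, 0] * c[:, 1]).mean()

        loo = np.array([cov01(np.delete(y, k, axis=0)) for k in range(3)])
        expected = 2 / 3 * np.sum((loo - loo.mean()) ** 2)
        assert jackknife_element_variance(y, 0, 1) == pytest.approx(expected)

    def test_requires_three_points(self):
        with pytest.raises(DataValidationError, match="T >= 3"):
            jackknife_element_variance(np.zeros((2, 2)), 0, 1)


class TestThresholdCovariance:
    def test_exact_zero_element_masked(self):
        # orthogonal contrast columns: sample covariance exactly 0
        y = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        cov, mask, stats = threshold_covariance(y, eta=0.05, multiplicity="none")
        assert cov[0, 1] == 0.0
        assert not mask[0, 1]
        assert stats[0].z_stat == 0.0

    def test_duplicated_channel_kept(self, rng):
        x = rng.standard_normal(100)
        y = np.column_stack([x, x])
        cov, mask, stats = threshold_covariance(y, eta=0.05, multiplicity="none")
        # oracle: pair statistic sqrt(T)*|sig|/delta
        sig = np.mean((x - x.mean()) ** 2)
        xx = (x - x.mean()) ** 2
        delta2 = np.mean((xx - xx.mean()) ** 2)
        z = np.sqrt(100) * sig / np.sqrt(delta2)
        assert stats[0].z_stat == pytest.approx(z)
        assert mask[0, 1] and cov[0, 1] == pytest.approx(sig)

    def test_null_calibration_rejection_rate(self, rng):
        # per-element level of the unadjusted test on N(0, I) data
        j, t, reps = 30, 200, 25
        n_off = j * (j - 1) // 2
        hits = 0
        for _ in range(reps):
            y = rng.standard_normal((t, j))
            _, mask, _ = threshold_covariance(y, eta=0.05, multiplicity="none")
            hits += int(np.triu(mask, k=1).sum())
        rate = hits / (reps * n_off)
        assert rate == pytest.approx(0.05, abs=0.012)

    def test_output_exactly_symmetric(self, rng):
        y = rng.standard_normal((80, 6))
        cov, mask, _ = threshold_covariance(y)
        assert np.array_equal(cov, cov.T)
        assert np.array_equal(mask, mask.T)
        assert np.diag(mask).all()

    def test_masks_nested_in_eta(self, rng):
        y = rng.standard_normal((150, 8)) @ np.diag([1, 2, 1, 1, 3, 1, 1, 1])
        prev = None
        for eta in (0.2, 0.1, 0.05, 0.01):
            _, mask, _ = threshold_covariance(y, eta=eta, multiplicity="none")
            if prev is not None:
                assert np.all(mask <= prev)
            prev = mask

    def test_frobenius_error_shrinks_with_t(self):
        true = np.array([[1.0, 0.6, 0.0], [0.6, 1.0, 0.0], [0.0, 0.0, 1.0]])
        chol = np.linalg.cholesky(true)
        errors = []
        rng = np.random.default_rng(5)
        for t in (100, 1000, 10000):
            y = rng.standard_normal((t, 3)) @ chol.T
            cov, _, _ = threshold_covariance(y, eta=0.05, multiplicity="none")
            errors.append(np.linalg.norm(cov - true))
        assert errors[0] > errors[1] > errors[2]

    def test_statistic_distribution_is_symmetric(self):
        # skewness of sqrt(T)(sig_hat - sig)/delta_hat under the CLT regime
        rng = np.random.default_rng(99)
        t, reps = 5000, 3000
        y = rng.standard_normal((reps, t, 2))
        c = y - y.mean(axis=1, keepdims=True)
        x = c[:, :, 0] * c[:, :, 1]
        sig = x.mean(axis=1)
        delta = np.sqrt(np.mean((x - sig[:, None]) ** 2, axis=1))
        stats_ = np.sqrt(t) * sig / delta
        m = stats_.mean()
        skew = np.mean((stats_ - m) ** 3) / np.std(stats_) ** 3
        assert abs(skew) < 0.1


class TestThresholdMean:
    def test_centered_data_masked_out(self, rng):
        j, t = 25, 2000
        y = rng.standard_normal((t, j))
        _, mask = threshold_mean(y, eta=0.05, multiplicity="none")
        assert mask.mean() <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / j)

    def test_strong_mean_kept(self, rng):
        y = rng.standard_normal((1000, 1)) + 1.0
        mean, mask = threshold_mean(y, eta=0.05, multiplicity="none")
        assert mask[0] and mean[0] == pytest.approx(1.0, abs=0.15)

    def test_zero_variance_nonzero_mean_kept(self):
        y = np.full((10, 1), 5.0)
        mean, mask = threshold_mean(y)
        assert mask[0] and mean[0] == 5.0


class TestEstimateSparseParams:
    def test_white_noise_mask_is_identity(self, rng):
        y = rng.standard_normal((1000, 10))
        params = estimate_sparse_params(y, eta=0.05)
        assert not params.mask.mean_mask.any()
        off = ~np.eye(10, dtype=bool)
        assert params.mask.cov_mask[off].mean() < 0.05
        assert np.diag(params.mask.cov_mask).all()

    def test_block_structure_recovered(self, rng):
        j = 6
        true = np.eye(j)
        for a in range(3):
            for b in range(3):
                if a != b:
                    true[a, b] = 0.8
        chol = np.linalg.cholesky(true)
        y = rng.standard_normal((1000, j)) @ chol.T
        params = estimate_sparse_params(y, eta=0.05)
        block = params.mask.cov_mask[:3, :3]
        assert block.all()  # 100% recovery of the strong block
        outside = params.mask.cov_mask[3:, :3]
        assert outside.mean() < 0.2

    def test_mask_consistency_invariant(self, rng):
        y = rng.standard_normal((200, 4)) + [0, 3, 0, 0]
        params = estimate_sparse_params(y)
        assert np.all(params.mean[~params.mask.mean_mask] == 0.0)
        assert np.all(params.cov[~params.mask.cov_mask] == 0.0)

    def test_jackknife_variance_route(self, rng):
        y = rng.standard_normal((300, 4))
        params = estimate_sparse_params(y, variance_method="jackknife")
        assert np.diag(params.mask.cov_mask).all()


class TestSparsityMask:
    def test_free_parameter_count(self):
        mask = SparsityMask([1, 0, 1], np.eye(3, dtype=bool))
        assert mask.n_free == 2 + 3
        full = SparsityMask.full(3)
        # J means + J(J+1)/2 upper-triangle entries
        assert full.n_free == 3 + 3 * 4 // 2

    def test_intersection(self):
        a = SparsityMask([1, 1], np.ones((2, 2), dtype=bool))
        m = np.eye(2, dtype=bool)
        b = SparsityMask([1, 0], m)
        c = a.intersect(b)
        assert list(c.mean_mask) == [True, False]
        assert np.array_equal(c.cov_mask, m)

    def test_rejects_asymmetric(self):
        bad = np.array([[1, 1], [0, 1]], dtype=bool)
        with pytest.raises(DataValidationError):
            SparsityMask([1, 1], bad)

    def test_rejects_pruned_diagonal(self):
        bad = np.array([[1, 0], [0, 0]], dtype=bool)
        with pytest.raises(DataValidationError):
            SparsityMask([1, 1], bad)


class TestTimeSeriesMatrix:
    def test_channel_name_mismatch(self):
        with pytest.raises(DataValidationError):
            TimeSeriesMatrix(np.zeros((3, 2)), channel_names=["a"])

    def test_shape_accessors(self):
        ts = TimeSeriesMatrix(np.zeros((5, 3)))
        assert (ts.T, ts.J) == (5, 3)
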