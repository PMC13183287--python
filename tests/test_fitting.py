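"""Fit metrics and sweep orchestration against brute-force oracles."""

import numpy as np
import pytest

from neuromass import (
    clarkson_similarity,
    cohens_d,
    grid_sweep,
    masked_dual_fit,
    ssim,
    strength_inhibition_slope,
)


class TestSSIM:
    def test_identity_is_one(self, rng):
        a = rng.standard_normal((20, 20))
        assert ssim(a, a) == pytest.approx(1.0)

    def test_symmetric(self, rng):
        a, b = rng.standard_normal((10, 10)), rng.standard_normal((10, 10))
        assert ssim(a, b) == pytest.approx(ssim(b, a))

    def test_constant_shift_matches_direct_formula(self, rng):
        a = rng.standard_normal((8, 8))
        b = a + 0.5
        # direct single-window formula with the same stabilizers
        L = max(a.max(), b.max()) - min(a.min(), b.min())
        c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
        mu_a, mu_b = a.mean(), b.mean()
        cov = ((a - mu_a) * (b - mu_b)).mean()
        expected = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
            (mu_a**2 + mu_b**2 + c1) * (a.var() + b.var() + c2)
        )
        val = ssim(a, b)
        assert val == pytest.approx(expected, rel=1e-12)
        assert val < 1.0

    def test_permutation_degrades(self, rng):
        a = rng.standard_normal((12, 12))
        perm = rng.permutation(12)
        assert ssim(a, a[perm][:, perm]) < ssim(a, a)

    def test_luminance_contrast_structure_factors(self, rng):
        """Windowed scikit-image SSIM agrees with the global form when the
        window covers the whole (border-free) matrix."""
        skimage = pytest.importorskip("skimage.metrics")
        a = rng.standard_normal((7, 7))
        b = a + 0.3 * rng.standard_normal((7, 7))
        L = max(a.max(), b.max()) - min(a.min(), b.min())
        got = skimage.structural_similarity(a, b, win_size=7, data_range=L)
        # same stabilizers, but skimage uses ddof=1 variances; rough parity
        assert ssim(a, b) == pytest.approx(got, abs=0.05)

    def test_shape_mismatch_and_degenerate(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((2, 2)), np.zeros((3, 3)))
        assert ssim(np.ones((3, 3)), np.ones((3, 3))) == 1.0


class TestClarkson:
    def test_equal_vectors(self):
        x = np.array([1.0, 2.0, 3.0])
        assert clarkson_similarity(x, x) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        x = rng.uniform(0.1, 1, 5)
        assert clarkson_similarity(x, 7.3 * x) == pytest.approx(1.0)
        y = rng.uniform(0.1, 1, 5)
        assert clarkson_similarity(x, y) == pytest.approx(
            clarkson_similarity(2 * x, 0.5 * y)
        )

    def test_orthonormal_value(self):
        x = np.array([1.0, 0.0])
        y = np.array([0.0, 1.0])
        assert clarkson_similarity(x, y) == pytest.approx(1 - np.sqrt(2) / 2)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            clarkson_similarity(np.zeros(3), np.ones(3))


class TestGridSweep:
    @staticmethod
    def _stub(seed, K, r_alpha):
        return {"score": K + r_alpha, "seed_echo": float(seed)}

    def test_single_cell(self):
        res = grid_sweep({"K": [0.5], "r_alpha": [0.25]}, self._stub, [0])
        assert len(res.rows) == 1
        assert res.rows[0]["score"] == pytest.approx(0.75)

    def test_grid_matches_closed_form(self):
        axes = {"K": [0.0, 0.5, 1.0], "r_alpha": [0.0, 1.0]}
        res = grid_sweep(axes, self._stub, [0, 1])
        grid = res.grid("score")
        expected = np.add.outer(np.array(axes["K"]), np.array(axes["r_alpha"]))
        assert np.allclose(grid, expected)

    def test_deterministic_repeat(self):
        axes = {"K": [0.1, 0.9], "r_alpha": [0.2, 0.8]}
        a = grid_sweep(axes, self._stub, [3, 4])
        b = grid_sweep(axes, self._stub, [3, 4])
        assert a.rows == b.rows

    def test_diverging_cell_recorded_not_fatal(self):
        def bad(seed, K):
            if K > 0.5:
                raise FloatingPointError("boom")
            return {"score": K}

        res = grid_sweep({"K": [0.0, 1.0]}, bad, [0])
        assert res.rows[0]["diverged"] is False
        assert res.rows[1]["diverged"] is True


class TestMaskedDualFit:
    def test_full_mask_is_plain_argmax(self, rng):
        fc = rng.random((5, 5))
        eeg = np.ones((5, 5))
        best = masked_dual_fit(fc, eeg, 0.85)
        assert best["index"] == tuple(np.unravel_index(np.argmax(fc), fc.shape))

    def test_mask_excludes_global_max(self):
        fc = np.array([[0.9, 0.2], [0.1, 0.5]])
        eeg = np.array([[0.1, 0.9], [0.9, 0.9]])
        best = masked_dual_fit(fc, eeg, 0.85)
        assert best["index"] == (1, 1)

    def test_matches_bruteforce_oracle(self, rng):
        fc = rng.random((8, 8))
        eeg = rng.random((8, 8))
        best = masked_dual_fit(fc, eeg, 0.5)
        candidates = [
            (fc[i, j], eeg[i, j], (-i, -j), (i, j))
            for i in range(8)
            for j in range(8)
            if eeg[i, j] >= 0.5
        ]
        oracle = max(candidates)[3]
        assert best["index"] == oracle

    def test_zero_threshold_degenerate_mask(self, rng):
        fc = rng.random((4, 4))
        eeg = rng.random((4, 4))
        best = masked_dual_fit(fc, eeg, 0.0)
        assert best["index"] == tuple(np.unravel_index(np.argmax(fc), fc.shape))

    def test_empty_mask_is_explicit(self):
        out = masked_dual_fit(np.ones((2, 2)), np.zeros((2, 2)), 0.85)
        assert out["feasible"] is False
        assert out["index"] is None


class TestCohensD:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cohens_d(x, x) == 0.0

    def test_one_pooled_sd_apart(self, rng):
        x = rng.standard_normal(100000)
        y = x - 1.0  # same variance, means one sample-SD apart
        assert cohens_d(x, y) == pytest.approx(1.0 / x.std(ddof=1), rel=1e-12)

    def test_very_large_threshold_sign(self, rng):
        x = rng.standard_normal(5000) + 1.5
        y = rng.standard_normal(5000)
        assert abs(cohens_d(x, y)) > 1.2  # "very large" band

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            cohens_d(np.array([1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            cohens_d(np.ones(5), np.ones(5))


class TestStrengthRegression:
    def test_exact_line(self):
        s = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept, r = strength_inhibition_slope(s, 2 * s + 1)
        assert (slope, intercept, r) == (
            pytest.approx(2.0), pytest.approx(1.0), pytest.approx(1.0)
        )

    def test_matches_normal_equations(self):
        s = np.array([0.5, 1.1, 2.0, 3.7])
        c = np.array([10.0, 12.0, 11.0, 17.0])
        X = np.column_stack([s, np.ones(4)])
        beta = np.linalg.solve(X.T @ X, X.T @ c)  # closed-form OLS
        slope, intercept, _ = strength_inhibition_slope(s, c)
        assert slope == pytest.approx(beta[0])
        assert intercept == pytest.approx(beta[1])

    def test_uncorrelated_slope_near_zero(self, rng):
        s = rng.uniform(1, 5, 5000)
        c = rng.uniform(10, 20, 5000)
        slope, _, r = strength_inhibition_slope(s, c)
        assert abs(r) < 0.05

    def test_constant_strength_rejected(self):
        with pytest.raises(ValueError):
            strength_inhibition_slope(np.ones(5), np.arange(5.0))
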