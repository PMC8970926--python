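"""Wavelet thresholding rules, threshold selection, noise estimation, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatigueeg.denoise import (
    ThresholdParams,
    benchmark_methods,
    denoise_signal,
    estimate_sigma,
    hard_threshold,
    improved_soft_threshold,
    level_threshold,
    rmse,
    snr,
    soft_threshold,
    wavelet_decompose,
)
from fatigueeg.errors import ParameterError


class TestDecomposition:
    def test_perfect_reconstruction(self, rng):
        x = rng.normal(0, 1, 1000)
        wc = wavelet_decompose(x, "db4", 3)
        assert wc.levels == 3
        rel = np.linalg.norm(wc.reconstruct(len(x)) - x) / np.linalg.norm(x)
        assert rel < 1e-8

    def test_zero_signal_zero_coeffs(self):
        wc = wavelet_decompose(np.zeros(256), "db4", 3)
        assert all(np.allclose(d, 0) for d in wc.details)
        assert np.allclose(wc.approx, 0)

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            wavelet_decompose(np.ones(4), "db4", 3)


class TestThresholdRules:
    def test_hard_closed_form(self):
        np.testing.assert_array_equal(
            hard_threshold(np.array([5.0, 1.0, -4.0]), 3.0), [5.0, 0.0, -4.0]
        )

    def test_hard_zero_lambda_is_identity(self, rng):
        d = rng.normal(0, 1, 100)
        np.testing.assert_array_equal(hard_threshold(d, 0.0), d)

    def test_hard_zeroes_exactly_subthreshold_entries(self, rng):
        d = rng.normal(0, 3, 1000)
        lam = 3.0
        out = hard_threshold(d, lam)
        # elementwise brute force
        for di, oi in zip(d, out):
            assert oi == (di if abs(di) >= lam else 0.0)

    def test_soft_closed_form(self):
        assert soft_threshold(np.array([5.0]), 3.0)[0] == 2.0
        assert soft_threshold(np.array([-5.0]), 3.0)[0] == -2.0
        assert soft_threshold(np.array([2.9]), 3.0)[0] == 0.0

    def test_soft_continuous_at_knot(self):
        lam = 3.0
        eps = 1e-9
        below = soft_threshold(np.array([lam - eps]), lam)[0]
        above = soft_threshold(np.array([lam + eps]), lam)[0]
        assert abs(above - below) < 1e-6

    def test_improved_hand_values(self):
        # large-coefficient branch: a lam^2 - lam + d
        out = improved_soft_threshold(np.array([5.0]), 3.0, 0.01)[0]
        assert out == pytest.approx(0.01 * 9 - 3 + 5, abs=1e-12)  # 2.09
        # interior branch: a d^2
        out = improved_soft_threshold(np.array([2.0]), 3.0, 0.01)[0]
        assert out == pytest.approx(0.01 * 4, abs=1e-12)  # 0.04

    def test_improved_reduces_to_soft_at_zero_shape(self, rng):
        d = rng.normal(0, 5, 10_000)
        for lam in [0.0, 1.0, 3.7]:
            np.testing.assert_array_equal(
                improved_soft_threshold(d, lam, 0.0), soft_threshold(d, lam)
            )

    def test_improved_continuous_everywhere(self):
        lam, a = 3.0, 0.05
        grid = np.concatenate(
            [
                np.linspace(-2 * lam, 2 * lam, 2001),
                lam + np.array([-1e-9, 0, 1e-9]),
                -lam + np.array([-1e-9, 0, 1e-9]),
            ]
        )
        grid.sort()
        out = improved_soft_threshold(grid, lam, a)
        assert np.max(np.abs(np.diff(out))) < np.max(np.diff(grid)) * 2 + 1e-9
        # jump across each knot specifically
        for knot in (lam, -lam):
            lo = improved_soft_threshold(np.array([knot - 1e-9]), lam, a)[0]
            hi = improved_soft_threshold(np.array([knot + 1e-9]), lam, a)[0]
            assert abs(hi - lo) < 1e-6

    def test_improved_side_condition_enforced(self):
        with pytest.raises(ParameterError):
            improved_soft_threshold(np.array([1.0]), 2.0, 0.6)

    @given(
        d=st.floats(-50, 50),
        lam=st.floats(0.1, 10),
        a_frac=st.floats(0, 0.99),
    )
    @settings(max_examples=200, deadline=None)
    def test_family_ordering(self, d, lam, a_frac):
        """|soft| <= |improved|; above the threshold also |improved| <= |hard|."""
        a = a_frac / lam
        dv = np.array([d])
        s = abs(soft_threshold(dv, lam)[0])
        i = abs(improved_soft_threshold(dv, lam, a)[0])
        h = abs(hard_threshold(dv, lam)[0])
        assert s <= i + 1e-12
        if abs(d) >= lam:
            assert i <= h + 1e-12

    def test_improved_approaches_hard_near_limit(self):
        lam = 2.0
        a = (1 - 1e-9) / lam
        d = np.array([lam + 1e-6])
        assert improved_soft_threshold(d, lam, a)[0] == pytest.approx(d[0], abs=1e-5)


class TestThresholdSelection:
    def test_zero_sigma_zero_threshold(self):
        for j in (1, 2, 3):
            assert level_threshold(0.0, j, 100) == 0.0

    def test_decreasing_in_level(self):
        lams = [level_threshold(1.0, j, 1000) for j in (1, 2, 3)]
        assert lams[0] > lams[1] > lams[2]

    def test_monotone_in_sigma_and_count(self):
        assert level_threshold(2.0, 1, 100) > level_threshold(1.0, 1, 100)
        assert level_threshold(1.0, 1, 1000) > level_threshold(1.0, 1, 100)

    def test_natural_log_closed_form(self):
        n = int(round(np.e**2))
        expected = np.sqrt(2 * np.log(n)) / np.log(2)
        assert level_threshold(1.0, 1, n) == pytest.approx(expected, rel=1e-12)
        # at N = e^2 exactly the value is 2/ln 2 (N rounds to 7, hence ~2%)
        assert expected == pytest.approx(2 / np.log(2), rel=0.02)

    def test_small_count_rejected(self):
        with pytest.raises(ParameterError):
            level_threshold(1.0, 1, 1)


class TestSigmaEstimate:
    def test_calibration_constant(self):
        d = np.full(100, 0.6745)
        assert estimate_sigma(d) == pytest.approx(1.0, rel=1e-12)

    def test_zero_coeffs(self):
        assert estimate_sigma(np.zeros(10)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            estimate_sigma(np.array([]))

    def test_gaussian_noise_monte_carlo(self):
        """Mean-abs estimator tracks sigma * sqrt(2/pi)/0.6745 over 100 seeds."""
        sigma = 2.0
        expected = sigma * np.sqrt(2 / np.pi) / 0.6745
        vals = []
        for seed in range(100):
            d = np.random.default_rng(seed).normal(0, sigma, 10_000)
            vals.append(estimate_sigma(d))
        assert abs(np.mean(vals) - expected) / expected < 0.1

    def test_sigma_from_level1_details_of_noise(self):
        """White noise in, level-1 details out: scale recovered within 10%."""
        sigma = 1.5
        vals = []
        for seed in range(100):
            x = np.random.default_rng(seed).normal(0, sigma, 4096)
            wc = wavelet_decompose(x, "db4", 3)
            vals.append(estimate_sigma(wc.details[0], mode="median"))
        assert abs(np.mean(vals) - sigma) / sigma < 0.1


class TestDenoisePipeline:
    def test_noiseless_smooth_signal_unchanged(self):
        t = np.linspace(0, 1, 2000)
        x = np.sin(2 * np.pi * 5 * t) + 0.5 * np.sin(2 * np.pi * 9 * t)
        for method in ("hard", "soft", "improved"):
            params = ThresholdParams(method=method)
            out, _ = denoise_signal(x, params)
            assert np.sqrt(np.mean((out - x) ** 2)) < 0.02 * np.sqrt(np.mean(x**2))

    def test_improved_a0_equals_soft_bitwise(self, rng):
        x = rng.normal(0, 1, 2000) + np.sin(np.linspace(0, 40, 2000))
        soft_out, _ = denoise_signal(x, ThresholdParams(method="soft"))
        imp_out, _ = denoise_signal(x, ThresholdParams(method="improved", a=0.0))
        np.testing.assert_array_equal(soft_out, imp_out)

    def test_zero_threshold_is_identity(self, rng):
        x = rng.normal(0, 1, 1024)
        params = ThresholdParams(method="soft", sigma=0.0)
        out, _ = denoise_signal(x, params)
        assert np.linalg.norm(out - x) / np.linalg.norm(x) < 1e-8

    def test_report_lambdas_per_level(self, rng):
        x = rng.normal(0, 1, 1024)
        _, rep = denoise_signal(x, ThresholdParams(method="hard"), J=3)
        assert len(rep.lambdas) == 3
        assert rep.sigma_hat > 0

    def test_benchmark_direction(self, clean_epochs_100):
        """Improved-soft wins mean SNR and mean RMSE on 100 noisy epochs."""
        res = benchmark_methods(clean_epochs_100[:30], noise_sd=5.0, seed=3)
        assert res.mean_snr["improved"] > res.mean_snr["hard"]
        assert res.mean_snr["improved"] > res.mean_snr["soft"]
        assert res.mean_rmse["improved"] < res.mean_rmse["hard"]
        assert res.mean_rmse["improved"] < res.mean_rmse["soft"]


class TestMetrics:
    def test_identical_signals(self):
        x = np.array([1.0, 2.0, 3.0])
        assert rmse(x, x) == 0.0
        assert snr(x, x) == np.inf

    def test_hand_arithmetic(self):
        x, xh = np.array([3.0, 4.0]), np.zeros(2)
        assert rmse(x, xh) == pytest.approx(np.sqrt(25 / 2))
        assert snr(x, xh) == pytest.approx(0.0, abs=1e-12)

    def test_doubling_noise_costs_6db(self, rng):
        x = rng.normal(0, 1, 1000)
        n = rng.normal(0, 0.1, 1000)
        drop = snr(x, x + n) - snr(x, x + 2 * n)
        assert drop == pytest.approx(20 * np.log10(2), abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            snr(np.ones(3), np.ones(4))
        with pytest.raises(ParameterError):
            rmse(np.ones(3), np.ones(4))
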