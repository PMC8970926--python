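"""Spectral feature extraction: STFT/PSD, band energies, ESD, EMD energies, HOS."""

import numpy as np
import pytest

from fatigueeg.errors import ParameterError
from fatigueeg.features import (
    ar_bispectrum,
    band_energy,
    emd_esd_features,
    esd,
    extract_features,
    hann_window,
    psd,
    psd_features,
    stft,
    third_order_cumulant,
)
from fatigueeg.preprocess import epoch_recording
from fatigueeg.recording import Epoch
from fatigueeg.synthetic import DEFAULT_BANDS


def make_epoch(data, rate=200.0):
    data = np.atleast_2d(data)
    return Epoch(data=data, rate=rate, subject_id="S01", state="normal", index=0)


class TestHannWindow:
    def test_endpoints_zero(self):
        w = hann_window(64)
        assert w[0] == 0.0 and w[-1] == 0.0

    def test_odd_length_midpoint_one(self):
        w = hann_window(65)
        assert w[32] == pytest.approx(1.0, abs=1e-12)

    def test_sin_squared_identity(self):
        n = np.arange(129)
        w = hann_window(129)
        np.testing.assert_allclose(w, np.sin(np.pi * n / 128) ** 2, atol=1e-12)

    def test_short_window_rejected(self):
        with pytest.raises(ParameterError):
            hann_window(1)


class TestSTFT:
    def test_matches_direct_summation(self, rng):
        """Frame-wise windowed DFT against an O(N^2) direct-sum oracle."""
        x = rng.normal(0, 1, 64)
        N, hop = 16, 8
        spec = stft(x, N, hop)
        w = hann_window(N)
        for m in range(spec.n_frames):
            frame = x[m * hop : m * hop + N] * w
            for k in range(N):
                direct = sum(
                    frame[n] * np.exp(-2j * np.pi * k * n / N) for n in range(N)
                )
                assert abs(spec.values[m, k] - direct) < 1e-9

    def test_frame_count(self, rng):
        x = rng.normal(0, 1, 1000)
        spec = stft(x, 200, 100)
        assert spec.n_frames == (1000 - 200) // 100 + 1

    def test_pure_sine_peaks_at_its_bin(self):
        rate, N = 200.0, 200
        t = np.arange(1000) / rate
        k0 = 10  # 10 Hz at 1 Hz resolution
        x = np.sin(2 * np.pi * k0 * t)
        spec = stft(x, N, N // 2, rate=rate)
        half = N // 2
        for m in range(spec.n_frames):
            assert np.argmax(np.abs(spec.values[m, :half])) == k0

    def test_zero_signal(self):
        spec = stft(np.zeros(100), 50, 25)
        assert np.allclose(spec.values, 0)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ParameterError):
            stft(np.ones(10), 20, 5)


class TestPSD:
    def test_nonnegative(self, rng):
        spec = stft(rng.normal(0, 1, 500), 100, 50)
        assert np.all(psd(spec) >= 0)

    def test_parseval_rectangular_single_frame(self, rng):
        """sum_k E(w_k)/N equals sum_n x[n]^2 for one unit-window frame."""
        x = rng.normal(0, 1, 128)
        spec = stft(x, 128, 128, window=None)
        assert spec.n_frames == 1
        E = np.abs(spec.values[0]) ** 2
        assert np.sum(E) / 128 == pytest.approx(np.sum(x**2), rel=1e-12)

    def test_amplitude_scaling_quadratic(self, rng):
        x = rng.normal(0, 1, 400)
        p1 = psd(stft(x, 100, 50))
        p2 = psd(stft(2 * x, 100, 50))
        np.testing.assert_allclose(p2, 4 * p1, rtol=1e-10)


class TestBandEnergy:
    def test_partition_additivity(self, rng):
        rate = 200.0
        p = psd(stft(rng.normal(0, 1, 600), 200, 100, rate=rate))
        full = band_energy(p, (0.0, 100.0), rate)
        parts = sum(
            band_energy(p, edges, rate)
            for edges in [(0.0, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 100.0)]
        )
        assert parts == pytest.approx(full, rel=1e-12)

    def test_sine_energy_lands_in_alpha(self):
        rate = 200.0
        t = np.arange(2000) / rate
        p = psd(stft(np.sin(2 * np.pi * 10 * t), 200, 100, rate=rate))
        alpha = band_energy(p, DEFAULT_BANDS["alpha"], rate)
        for name, edges in DEFAULT_BANDS.items():
            if name != "alpha":
                assert alpha > 100 * band_energy(p, edges, rate)

    def test_empty_band_is_zero(self, rng):
        p = psd(stft(rng.normal(0, 1, 300), 100, 50, rate=200.0))
        # bins sit at multiples of 2 Hz; (50.5, 51.5) contains none of them
        assert band_energy(p, (50.5, 51.5), 200.0) == 0.0

    def test_band_outside_nyquist_rejected(self, rng):
        p = psd(stft(rng.normal(0, 1, 300), 100, 50, rate=200.0))
        with pytest.raises(ParameterError):
            band_energy(p, (90.0, 150.0), 200.0)


class TestFeatureVectors:
    def test_psd_feature_count_and_names(self, one_recording):
        ep = epoch_recording(one_recording, 10.0)[0]
        fv = psd_features(ep)
        assert len(fv.values) == ep.n_channels * len(DEFAULT_BANDS)
        assert fv.feature_names[0] == "ch0:delta"

    def test_emd_feature_count_96_at_32_channels(self, rng):
        data = rng.normal(0, 1, (32, 400))
        fv = emd_esd_features(make_epoch(data), n_imfs=3)
        assert len(fv.values) == 96

    def test_zero_epoch_zero_features(self):
        fv = emd_esd_features(make_epoch(np.zeros((2, 400))), n_imfs=3)
        assert np.all(fv.values == 0)

    def test_scale_equivariance(self, rng):
        data = rng.normal(0, 1, (2, 400))
        f1 = psd_features(make_epoch(data)).values
        f2 = psd_features(make_epoch(3 * data)).values
        np.testing.assert_allclose(f2, 9 * f1, rtol=1e-9)

    def test_determinism(self, one_recording):
        ep = epoch_recording(one_recording, 10.0)[0]
        a = emd_esd_features(ep, n_imfs=3).values
        b = emd_esd_features(ep, n_imfs=3).values
        np.testing.assert_array_equal(a, b)

    def test_imf_energy_bounded_by_signal_energy(self):
        """Near-orthogonal tones: IMF energies stay below total (Parseval)."""
        t = np.arange(0, 5, 1 / 200)
        x = np.sin(2 * np.pi * 20 * t) + np.sin(2 * np.pi * 2 * t)
        fv = emd_esd_features(make_epoch(x), n_imfs=3)
        total = len(t) * np.sum(x**2) / (2 * np.pi)
        assert np.sum(fv.values) <= 1.1 * total

    def test_feature_matrix_from_epochs(self, small_dataset):
        from fatigueeg.preprocess import preprocess_recording
        from fatigueeg.recording import EpochSet

        eps = EpochSet()
        for rec in small_dataset:
            eps = eps.extend(preprocess_recording(rec, target_rate=None))
        fm = extract_features(eps, method="psd")
        assert fm.n_epochs == len(eps)
        assert fm.n_features == 4 * 5
        assert fm.feature_names[0] == "Fp1:delta"
        assert set(fm.labels) == {"normal", "fatigue"}

    def test_theta_feature_separates_states(self, small_dataset):
        """A threshold on mean theta power separates >= 80% of epochs."""
        from fatigueeg.preprocess import preprocess_recording
        from fatigueeg.recording import EpochSet

        eps = EpochSet()
        for rec in small_dataset:
            eps = eps.extend(preprocess_recording(rec, target_rate=None))
        fm = extract_features(eps, method="psd")
        theta_cols = [i for i, nm in enumerate(fm.feature_names) if nm.endswith("theta")]
        total = fm.values.sum(axis=1)
        score = fm.values[:, theta_cols].sum(axis=1) / total
        thresh = np.median(score)
        pred = np.where(score > thresh, "fatigue", "normal")
        assert np.mean(pred == fm.labels) >= 0.8


class TestESD:
    def test_zero_signal(self):
        assert np.allclose(esd(np.zeros(64)), 0)

    def test_parseval(self, rng):
        x = rng.normal(0, 1, 256)
        assert np.sum(esd(x)) == pytest.approx(
            256 * np.sum(x**2) / (2 * np.pi), rel=1e-12
        )

    def test_shift_invariance(self, rng):
        x = rng.normal(0, 1, 128)
        np.testing.assert_allclose(esd(x), esd(np.roll(x, 17)), atol=1e-9)


class TestHigherOrderSpectra:
    def test_hand_example(self):
        cum = third_order_cumulant(np.array([1.0, 2.0, 3.0]), M=3, p_lags=1)
        assert cum.value(0, 0) == pytest.approx(12.0, rel=1e-12)

    def test_symmetry(self, rng):
        x = rng.normal(0, 1, 300)
        cum = third_order_cumulant(x, M=100, p_lags=5)
        np.testing.assert_allclose(cum.r_hat, cum.r_hat.T, atol=1e-10)

    def test_gaussian_cumulants_shrink_with_averaging(self):
        """Third cumulants of Gaussian noise vanish as segments accumulate."""
        wins = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(0, 1, 2000)
            r_many = third_order_cumulant(x, M=20, p_lags=0).value(0, 0)
            r_one = third_order_cumulant(x[:20], M=20, p_lags=0).value(0, 0)
            if abs(r_many) < abs(r_one):
                wins += 1
        assert wins >= 90

    def test_non_divisible_length_rejected(self):
        with pytest.raises(ParameterError):
            third_order_cumulant(np.ones(10), M=3, p_lags=1)

    def test_ar_order_zero_constant(self, rng):
        x = rng.normal(0, 1, 300) ** 3  # skewed
        cum = third_order_cumulant(x, M=100, p_lags=2)
        B = ar_bispectrum(cum, p=0)
        assert np.allclose(B, B.flat[0])

    def test_bispectrum_symmetric_in_frequencies(self, rng):
        x = rng.normal(0, 1, 400) ** 3
        cum = third_order_cumulant(x, M=100, p_lags=3)
        B = ar_bispectrum(cum, p=2)
        np.testing.assert_allclose(B, B.T, atol=1e-10)
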