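"""Time-frequency transforms against independent numerical oracles."""

import numpy as np
import pytest

from eegfusion.core import MONTAGE_19
from eegfusion.emd import emd
from eegfusion.timefreq import (CWTConfig, HilbertConfig, STFTConfig,
                                build_stack, compute_scalogram,
                                compute_spectrogram, hilbert_spectrum,
                                make_scale_grid, morse_freq_response,
                                morse_peak_omega, scale_to_frequency,
                                stft_segment_count, to_grayscale_image)

FS = 500.0


def brute_force_spectrogram(x, cfg, fs):
    """Direct windowed-DFT sum: independent of any FFT routine."""
    from scipy.signal.windows import hamming

    M = cfg.window_samples(fs)
    R = cfg.hop_samples(fs)
    win = hamming(M, sym=True)
    k = (len(x) - (M - R)) // R
    n = np.arange(M)
    bins = np.arange(cfg.n_fft // 2 + 1)
    freqs = bins * fs / cfg.n_fft
    keep = (freqs >= cfg.f_lo) & (freqs <= cfg.f_hi)
    dft = np.exp(-2j * np.pi * np.outer(bins[keep], n) / cfg.n_fft)
    out = np.empty((keep.sum(), k))
    for m in range(k):
        seg = x[m * R : m * R + M] * win
        out[:, m] = np.abs(dft @ seg) ** 2
    return out


class TestSpectrogram:
    def test_default_shape_is_92_by_126(self, rng):
        S = compute_spectrogram(rng.standard_normal(2000), fs=FS)
        assert S.shape == (92, 126)

    def test_zero_signal_gives_zero_matrix(self):
        assert np.allclose(compute_spectrogram(np.zeros(2000), fs=FS), 0.0)

    def test_tone_peaks_at_nearest_bin(self):
        t = np.arange(2000) / FS
        S = compute_spectrogram(np.sin(2 * np.pi * 10 * t), fs=FS)
        freqs = np.arange(1, 93) * FS / 1024
        expected_bin = np.argmin(np.abs(freqs - 10.0))
        assert np.all(S.argmax(axis=0) == expected_bin)

    def test_matches_brute_force_dft_oracle(self, rng):
        cfg = STFTConfig()
        for _ in range(5):
            x = rng.standard_normal(2000)
            fast = compute_spectrogram(x, cfg, FS)
            slow = brute_force_spectrogram(x, cfg, FS)
            assert np.max(np.abs(fast - slow)) <= 1e-10 * np.max(slow)

    def test_window_longer_than_frame_raises(self):
        with pytest.raises(ValueError, match="window"):
            compute_spectrogram(np.zeros(100), STFTConfig(), FS)

    def test_segment_count_formula_matches_enumeration(self, rng):
        for _ in range(200):
            nx = int(rng.integers(100, 5000))
            m = int(rng.integers(10, nx + 1))
            r = int(rng.integers(1, m + 1))
            expected = len([s for s in range(0, nx, r) if s + m <= nx])
            assert stft_segment_count(nx, m, r) == expected


class TestScaleGrid:
    def test_122_scales_starting_near_0022(self):
        scales = make_scale_grid()
        assert scales.size == 122
        assert scales[0] == pytest.approx(1 / 45.0, rel=1e-12)
        assert round(scales[0], 3) == 0.022

    def test_grid_is_geometric_and_spans_the_band(self):
        scales = make_scale_grid()
        ratios = scales[1:] / scales[:-1]
        assert np.allclose(ratios, ratios[0], atol=1e-12)
        freqs = scale_to_frequency(scales)
        assert freqs[0] == pytest.approx(45.0)
        assert freqs[-1] == pytest.approx(0.45)


def time_domain_morse(scale, beta, gamma, lags, f_max=60.0, df=0.02):
    """Wavelet waveform by dense trapezoidal inverse-Fourier integration."""
    omega = 2 * np.pi * np.arange(df, f_max, df)
    psi_hat = morse_freq_response(omega, scale, beta, gamma)
    kernel = np.exp(1j * np.outer(lags, omega))
    return np.trapezoid(kernel * psi_hat, omega, axis=1) / (2 * np.pi)


class TestScalogram:
    def test_default_shape_is_122_by_2000(self, rng):
        W = compute_scalogram(rng.standard_normal(2000), fs=FS)
        assert W.shape == (122, 2000)

    def test_zero_signal_gives_zero_magnitudes(self):
        assert np.allclose(compute_scalogram(np.zeros(2000), fs=FS), 0.0)

    def test_sign_invariance_of_magnitude(self, rng):
        x = rng.standard_normal(2000)
        assert np.allclose(compute_scalogram(x, fs=FS),
                           compute_scalogram(-x, fs=FS), atol=1e-12)

    def test_tone_peaks_within_one_scale_step(self):
        t = np.arange(2000) / FS
        W = compute_scalogram(np.sin(2 * np.pi * 10 * t), fs=FS)
        freqs = scale_to_frequency(make_scale_grid())
        peak = freqs[W.mean(axis=1).argmax()]
        step = freqs[0] / freqs[1]
        assert 10.0 / step <= peak <= 10.0 * step

    @pytest.mark.parametrize("f0", [5.0, 10.0, 20.0])
    def test_centre_values_match_convolution_integral(self, f0):
        """Oracle: trapezoidal integration of the time-domain convolution."""
        cfg = CWTConfig()
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * f0 * t)
        W = compute_scalogram(x, cfg, FS)
        scales = make_scale_grid(cfg)
        b = 1000  # centre of the frame
        si = int(np.argmin(np.abs(scale_to_frequency(scales) - f0)))
        for j in (si - 3, si, si + 3):
            s = scales[j]
            lags = (np.arange(2000) - b) / FS
            psi = time_domain_morse(s, cfg.morse_beta, cfg.morse_gamma, lags)
            oracle = np.abs(np.trapezoid(x * np.conj(psi), t))
            assert W[j, b] == pytest.approx(oracle, rel=0.01)

    def test_empty_signal_raises(self):
        with pytest.raises(ValueError):
            compute_scalogram(np.array([]), fs=FS)


class TestMorseWavelet:
    def test_peak_location_and_value(self):
        beta, gamma = 20.0, 3.0
        s = 0.1
        omega = np.linspace(1.0, 200.0, 20000)
        resp = morse_freq_response(omega, s, beta, gamma)
        peak_omega = omega[resp.argmax()]
        assert peak_omega == pytest.approx(2 * np.pi / s, rel=1e-3)
        assert resp.max() == pytest.approx(2.0, rel=1e-6)
        assert np.all(morse_freq_response(-omega, s, beta, gamma) == 0.0)


class TestEMD:
    def test_reconstruction_identity_random_signals(self, rng):
        for _ in range(20):
            x = rng.standard_normal(2000)
            imfs, res = emd(x)
            rebuilt = np.sum(imfs, axis=0) + res
            assert np.linalg.norm(rebuilt - x) <= 1e-8 * np.linalg.norm(x)

    def test_pure_tone_is_captured_by_first_imf(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 10 * t)
        imfs, res = emd(x)
        assert len(imfs) >= 1
        assert np.corrcoef(imfs[0], x)[0, 1] > 0.99
        assert np.sqrt(np.mean(res ** 2)) < 0.01 * np.sqrt(np.mean(x ** 2))

    def test_two_tone_mixture_separates_fast_component(self):
        t = np.arange(2000) / FS
        fast = np.sin(2 * np.pi * 20 * t)
        x = np.sin(2 * np.pi * 2 * t) + fast
        imfs, _ = emd(x)
        core = slice(200, 1800)  # central 80 %
        assert np.corrcoef(imfs[0][core], fast[core])[0, 1] > 0.95

    def test_constant_signal_yields_no_imfs(self):
        imfs, res = emd(np.full(500, 3.3))
        assert imfs == []
        assert np.allclose(res, 3.3)

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError):
            emd(np.array([]))
        with pytest.raises(ValueError):
            emd(np.array([1.0, np.nan, 2.0]))


class TestHilbertSpectrum:
    def test_grid_has_128_points(self):
        grid = HilbertConfig().grid()
        assert grid.size == 128
        assert grid[0] == pytest.approx(0.45)
        assert grid[-1] == pytest.approx(44.9)

    def test_default_shape_is_128_by_2000(self, rng):
        H = hilbert_spectrum(rng.standard_normal(2000), fs=FS)
        assert H.shape == (128, 2000)

    def test_zero_signal_gives_zero_matrix(self):
        assert np.allclose(hilbert_spectrum(np.zeros(2000), fs=FS), 0.0)

    def test_tone_mass_concentrates_at_its_frequency(self):
        cfg = HilbertConfig()
        t = np.arange(2000) / FS
        H = hilbert_spectrum(np.sin(2 * np.pi * 10 * t), cfg, FS)
        grid = cfg.grid()
        b = np.argmin(np.abs(grid - 10.0))
        core = slice(200, 1800)
        frac = H[b - 1 : b + 2, core].sum() / H[:, core].sum()
        assert frac >= 0.95

    def test_deposited_mass_never_exceeds_instantaneous_amplitude(self, rng):
        from eegfusion.timefreq import instantaneous_freq_amp

        cfg = HilbertConfig()
        x = rng.standard_normal(2000)
        H = hilbert_spectrum(x, cfg, FS)
        imfs, _ = emd(x, max_imfs=cfg.max_imfs, sd_threshold=cfg.sift_tolerance)
        total_amp = sum(instantaneous_freq_amp(i, FS)[1].sum() for i in imfs)
        assert H.sum() <= total_amp + 1e-9


class TestGrayscale:
    def test_constant_matrix_maps_to_zeros(self):
        img = to_grayscale_image(np.full((50, 60), 4.2))
        assert img.shape == (128, 128)
        assert np.allclose(img, 0.0)

    def test_output_contract_bounds_and_shape(self, rng):
        img = to_grayscale_image(np.abs(rng.standard_normal((92, 126))), use_log=True)
        assert img.shape == (128, 128)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_gradient_monotonicity_survives_resize(self):
        gradient = np.tile(np.linspace(0, 1, 256), (256, 1))
        img = to_grayscale_image(gradient)
        assert np.all(np.diff(img, axis=1) >= -1e-9)

    def test_nonfinite_input_raises(self):
        bad = np.ones((10, 10))
        bad[3, 3] = np.inf
        with pytest.raises(ValueError):
            to_grayscale_image(bad)


class TestBuildStack:
    def test_shapes_and_channel_permutation(self, rng):
        frame = rng.standard_normal((19, 2000))
        st = build_stack(frame, fs=FS)
        for mod in (st.spectrogram, st.scalogram, st.hilbert):
            assert mod.shape == (128, 128, 19)
            assert mod.min() >= 0.0 and mod.max() <= 1.0
        perm = rng.permutation(19)
        st_perm = build_stack(frame[perm], fs=FS)
        assert np.allclose(st_perm.spectrogram, st.spectrogram[:, :, perm])
        assert np.allclose(st_perm.hilbert, st.hilbert[:, :, perm])

    def test_zero_frame_gives_zero_stacks(self):
        st = build_stack(np.zeros((19, 2000)), fs=FS)
        assert np.allclose(st.spectrogram, 0.0)
        assert np.allclose(st.scalogram, 0.0)
        assert np.allclose(st.hilbert, 0.0)

    def test_wrong_channel_count_raises(self, rng):
        with pytest.raises(ValueError, match="19"):
            build_stack(rng.standard_normal((5, 2000)), fs=FS)
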