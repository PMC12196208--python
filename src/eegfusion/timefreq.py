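"""Time-frequency representations of a 4 s EEG frame.

Three complementary maps are computed per channel and standardised to a
128x128 grayscale image:

* spectrogram — squared-magnitude short-time Fourier transform (Hamming
  window, 1 s / 0.024 s hop, 1024-point FFT, 0.45-45 Hz band);
* scalogram — magnitude of the continuous wavelet transform on a grid of
  122 geometrically spaced scales with a generalized Morse wavelet;
* Hilbert spectrum — instantaneous amplitude of each empirical mode
  deposited at its instantaneous frequency on a 128-point (0.35 Hz step)
  frequency grid.

Stacking the 19 channels depth-wise yields the 128x128x19 inputs consumed
by the CNN feature extractors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import hilbert as analytic_signal
from scipy.signal.windows import hamming
from skimage.transform import resize as _sk_resize

from .core import MONTAGE_19
from .emd import emd


# ---------------------------------------------------------------------------
# configuration

@dataclass
class STFTConfig:
    """Short-time Fourier transform settings.

    With the defaults at fs=500 Hz and a 2000-sample frame, the window is
    M=500 samples, the hop R=12 samples, giving k = (Nx-(M-R))/R = 126
    segments and 92 retained frequency bins (centres within 0.45-45 Hz).
    """

    window_length_s: float = 1.0
    hop_s: float = 0.024
    n_fft: int = 1024
    f_lo: float = 0.45
    f_hi: float = 45.0

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_length_s * fs))

    def hop_samples(self, fs: float) -> int:
        return int(round(self.hop_s * fs))


@dataclass
class CWTConfig:
    """Continuous wavelet transform settings (generalized Morse wavelet).

    ``n_scales`` geometrically spaced scales span centre frequencies from
    ``f_hi`` down to ``f_lo``; the smallest scale is 1/f_hi (~0.022 s at
    45 Hz). ``morse_gamma=3, morse_beta=20`` give the symmetric
    time-bandwidth-60 Morse wavelet common in clinical-EEG practice.
    """

    n_scales: int = 122
    f_lo: float = 0.45
    f_hi: float = 45.0
    morse_gamma: float = 3.0
    morse_beta: float = 20.0


@dataclass
class HilbertConfig:
    """Hilbert-spectrum settings: EMD sifting plus the deposit grid.

    The frequency grid is ``f_lo + m * f_step`` for every m keeping the
    value at or below ``f_hi`` — 128 points with the defaults.
    """

    f_lo: float = 0.45
    f_hi: float = 45.0
    f_step: float = 0.35
    max_imfs: int = 10
    sift_tolerance: float = 0.2

    def grid(self) -> np.ndarray:
        m = int(np.floor((self.f_hi - self.f_lo) / self.f_step + 1e-9)) + 1
        return self.f_lo + self.f_step * np.arange(m)


@dataclass
class TFRStack:
    """Per-frame triple of 128x128x19 grayscale stacks (values in [0, 1])."""

    spectrogram: np.ndarray
    scalogram: np.ndarray
    hilbert: np.ndarray
    subject_id: str = ""
    frame_index: int = 0
    label: str = "unknown"


# ---------------------------------------------------------------------------
# spectrogram

def stft_segment_count(n_samples: int, window: int, hop: int) -> int:
    """k = (Nx - (M - R)) / R, truncated: the number of full windows."""
    if window > n_samples:
        raise ValueError("window longer than the frame")
    return (n_samples - (window - hop)) // hop


def stft_band_bins(cfg: STFTConfig, fs: float) -> np.ndarray:
    """FFT bin indices whose centre frequency lies in [f_lo, f_hi]."""
    freqs = np.arange(cfg.n_fft // 2 + 1) * fs / cfg.n_fft
    return np.where((freqs >= cfg.f_lo) & (freqs <= cfg.f_hi))[0]


def compute_spectrogram(frame_channel: np.ndarray, cfg: STFTConfig | None = None,
                        fs: float = 500.0) -> np.ndarray:
    """Squared-magnitude STFT restricted to the analysis band.

    Returns ``[n_band_bins x k]`` with rows ordered low to high frequency;
    92 x 126 with the defaults on a 4 s frame at 500 Hz.
    """
    cfg = cfg or STFTConfig()
    x = np.asarray(frame_channel, dtype=np.float64)
    M = cfg.window_samples(fs)
    R = cfg.hop_samples(fs)
    if M > x.size:
        raise ValueError(f"window ({M} samples) longer than frame ({x.size})")
    win = hamming(M, sym=True)
    segments = sliding_window_view(x, M)[::R] * win[None, :]
    spectra = np.fft.rfft(segments, n=cfg.n_fft, axis=1)
    power = np.abs(spectra) ** 2
    bins = stft_band_bins(cfg, fs)
    return power[:, bins].T


# ---------------------------------------------------------------------------
# scalogram

def morse_peak_omega(beta: float, gamma: float) -> float:
    """Angular frequency at which the Morse frequency response peaks."""
    return (beta / gamma) ** (1.0 / gamma)


def make_scale_grid(cfg: CWTConfig | None = None) -> np.ndarray:
    """Geometric scale grid whose centre frequencies run f_hi down to f_lo.

    Scales are defined so that a wavelet at scale s has centre frequency
    1/s; hence s0 = 1/f_hi (~0.0222 s at 45 Hz) and the largest scale is
    1/f_lo.
    """
    cfg = cfg or CWTConfig()
    s0 = 1.0 / cfg.f_hi
    s_max = 1.0 / cfg.f_lo
    return s0 * (s_max / s0) ** (np.arange(cfg.n_scales) / (cfg.n_scales - 1))


def scale_to_frequency(scales: np.ndarray) -> np.ndarray:
    """Centre frequency (Hz) of each scale under this package's convention."""
    return 1.0 / np.asarray(scales)


def morse_freq_response(omega: np.ndarray, scale: float, beta: float,
                        gamma: float) -> np.ndarray:
    """Frequency response of the scaled Morse wavelet, peak value 2 at f=1/s.

    The mother wavelet is the analytic Morse window a * w^beta * exp(-w^gamma)
    (zero for w <= 0); the scale maps its peak to angular frequency 2*pi/s.
    Evaluated in log space to stay finite at large beta.
    """
    om_p = morse_peak_omega(beta, gamma)
    x = np.asarray(omega, dtype=np.float64) * scale * om_p / (2.0 * np.pi)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = 2.0 * np.exp(
        beta * np.log(x[pos] / om_p) - x[pos] ** gamma + om_p ** gamma
    )
    return out


def compute_scalogram(frame_channel: np.ndarray, cfg: CWTConfig | None = None,
                      fs: float = 500.0) -> np.ndarray:
    """Morse-wavelet CWT magnitude at every (scale, time) pair.

    One time shift per sample; shape ``[n_scales x n_samples]`` (122 x 2000
    with the defaults), row 0 = smallest scale = highest frequency. Edge
    effects are reduced by reflect-padding with half the frame length per
    side before the FFT-domain filtering.
    """
    cfg = cfg or CWTConfig()
    x = np.asarray(frame_channel, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty signal")
    n = x.size
    pad = n // 2
    xp = np.pad(x, pad, mode="reflect") if n > 1 else x
    np_tot = xp.size
    X = np.fft.fft(xp)
    omega = 2.0 * np.pi * np.fft.fftfreq(np_tot, d=1.0 / fs)
    scales = make_scale_grid(cfg)
    out = np.empty((cfg.n_scales, n), dtype=np.float64)
    for i, s in enumerate(scales):
        psi = morse_freq_response(omega, s, cfg.morse_beta, cfg.morse_gamma)
        w = np.fft.ifft(X * psi)
        out[i] = np.abs(w[pad : pad + n])
    return out


# ---------------------------------------------------------------------------
# Hilbert spectrum

def instantaneous_freq_amp(imf: np.ndarray, fs: float):
    """Instantaneous frequency (Hz) and amplitude of one IMF.

    The analytic signal gives amplitude and phase; frequency is the central
    difference of the unwrapped phase (one-sided at the endpoints) divided
    by 2*pi.
    """
    z = analytic_signal(imf)
    amp = np.abs(z)
    phase = np.unwrap(np.angle(z))
    freq = np.gradient(phase) * fs / (2.0 * np.pi)
    return freq, amp


def hilbert_spectrum(frame_channel: np.ndarray, cfg: HilbertConfig | None = None,
                     fs: float = 500.0) -> np.ndarray:
    """Amplitude Hilbert spectrum on the fixed frequency grid.

    Each IMF's instantaneous amplitude is deposited in the nearest grid bin
    at each time sample, summed across IMFs; frequencies farther than half
    a grid step outside the band are discarded. Shape
    ``[n_grid x n_samples]`` (128 x 2000 with the defaults), row 0 = lowest
    frequency.
    """
    cfg = cfg or HilbertConfig()
    x = np.asarray(frame_channel, dtype=np.float64)
    grid = cfg.grid()
    H = np.zeros((grid.size, x.size), dtype=np.float64)
    if x.size == 0 or np.allclose(x, x.flat[0]):
        return H
    imfs, _ = emd(x, max_imfs=cfg.max_imfs, sd_threshold=cfg.sift_tolerance)
    t = np.arange(x.size)
    for imf in imfs:
        freq, amp = instantaneous_freq_amp(imf, fs)
        idx = np.round((freq - cfg.f_lo) / cfg.f_step).astype(int)
        ok = (idx >= 0) & (idx < grid.size)
        # also require the frequency itself within half a step of the band
        ok &= (freq >= cfg.f_lo - cfg.f_step / 2) & (freq <= grid[-1] + cfg.f_step / 2)
        np.add.at(H, (idx[ok], t[ok]), amp[ok])
    return H


# ---------------------------------------------------------------------------
# grayscale standardisation and stacking

def to_grayscale_image(tfr: np.ndarray, use_log: bool = False,
                       size: int = 128, eps: float = 1e-12) -> np.ndarray:
    """Standardise a TFR matrix to a ``size x size`` grayscale image in [0,1].

    Optional log10(x+eps) compression, per-image min-max normalisation
    (a constant image maps to all zeros), then bilinear resize. Row 0 is
    the lowest frequency; columns are time ascending.
    """
    tfr = np.asarray(tfr, dtype=np.float64)
    if tfr.size == 0:
        raise ValueError("empty TFR matrix")
    if not np.all(np.isfinite(tfr)):
        raise ValueError("TFR matrix contains non-finite values")
    img = np.log10(tfr + eps) if use_log else tfr
    lo, hi = img.min(), img.max()
    img = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    if img.shape != (size, size):
        img = _sk_resize(img, (size, size), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    return np.clip(img, 0.0, 1.0)


def build_stack(frame: np.ndarray, fs: float = 500.0,
                stft_cfg: STFTConfig | None = None,
                cwt_cfg: CWTConfig | None = None,
                hilbert_cfg: HilbertConfig | None = None,
                subject_id: str = "", frame_index: int = 0,
                label: str = "unknown", size: int = 128,
                log_spectrogram: bool = False, log_scalogram: bool = False,
                log_hilbert: bool = False) -> TFRStack:
    """Compute the three 128x128x19 grayscale stacks for one multichannel frame.

    All three maps are min-max normalised on a linear intensity scale by
    default: a band-limited EEG power map spans many decades, so log
    compression followed by per-image min-max squeezes physiologically
    meaningful band-power contrasts into a few grey levels; the linear
    mapping keeps them as first-order brightness differences. Log
    compression remains available per modality for visual inspection.
    Depth order equals the montage channel order of the input rows.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2 or frame.shape[0] != len(MONTAGE_19):
        raise ValueError(f"expected [{len(MONTAGE_19)} x n] frame, got {frame.shape}")
    n_ch = frame.shape[0]
    spec = np.empty((size, size, n_ch))
    scal = np.empty((size, size, n_ch))
    hil = np.empty((size, size, n_ch))
    for c in range(n_ch):
        s = compute_spectrogram(frame[c], stft_cfg, fs)
        spec[:, :, c] = to_grayscale_image(s, use_log=log_spectrogram, size=size)
        w = compute_scalogram(frame[c], cwt_cfg, fs)
        # scale rows run high->low frequency; flip so row 0 = lowest
        scal[:, :, c] = to_grayscale_image(w[::-1], use_log=log_scalogram, size=size)
        h = hilbert_spectrum(frame[c], hilbert_cfg, fs)
        hil[:, :, c] = to_grayscale_image(h, use_log=log_hilbert, size=size)
    return TFRStack(spectrogram=spec, scalogram=scal, hilbert=hil,
                    subject_id=subject_id, frame_index=frame_index, label=label)
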