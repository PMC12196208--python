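"""Synthetic labeled EEG cohorts with class-conditional spectral structure.

Each subject is 19 channels of 1/f background noise plus amplitude-modulated
band-limited oscillators (delta/theta/alpha/beta). Class signatures shift the
band powers:

* class "A" mimics AD-typical EEG slowing — theta power raised and alpha
  power lowered, across the scalp (theta/alpha power ratio doubles at
  ``effect_size=1``);
* class "F" raises theta on the frontal electrodes only (Fp1, Fp2, F3, F7,
  F8), giving channel-importance analyses a known ground truth;
* class "C" is the unmodified baseline.

Between-subject variability is lognormal on band power; every signal is
deterministic given ``(spec.seed, subject_seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CLASS_LABELS, FRONTAL_CHANNELS, MONTAGE_19, EEGRecording, write_edf

#: Canonical EEG bands, Hz.
BANDS = {"delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
         "beta": (13.0, 30.0)}

#: Baseline relative band powers of an eyes-closed resting adult EEG.
BASELINE_BAND_POWER = {"delta": 1.0, "theta": 1.0, "alpha": 2.0, "beta": 0.5}


@dataclass
class SyntheticSpec:
    """Study-condition parameters of a synthetic cohort.

    ``effect_size`` scales the class signatures: 0 makes all classes
    generatively identical (a null cohort); 1 doubles the class-A
    theta/alpha power ratio relative to class C, and doubles frontal theta
    for class F.
    """

    n_subjects_per_class: int = 8
    classes: tuple = CLASS_LABELS
    duration_s: float = 30.0
    fs: float = 500.0
    band_powers: dict = field(default_factory=lambda: dict(BASELINE_BAND_POWER))
    effect_size: float = 1.0
    subject_sd: float = 0.1
    noise_exponent: float = 1.0
    osc_to_noise: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if any(p < 0 for p in self.band_powers.values()):
            raise ValueError("band powers must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.fs <= 2 * max(hi for _, hi in BANDS.values()):
            raise ValueError("fs must exceed twice the highest band edge")
        for c in self.classes:
            if c not in CLASS_LABELS:
                raise ValueError(f"unknown class {c!r}")


def class_band_multipliers(label: str, effect_size: float):
    """Per-band power multipliers (global, frontal) for one class."""
    e = effect_size
    glob = {b: 1.0 for b in BANDS}
    front = {b: 1.0 for b in BANDS}
    if label == "A":
        # diffuse EEG slowing: slow bands up, fast bands down; the
        # theta/alpha power ratio doubles at e = 1
        glob["delta"] = 2.0 ** (0.5 * e)
        glob["theta"] = 2.0 ** (0.5 * e)
        glob["alpha"] = 2.0 ** (-0.5 * e)
        glob["beta"] = 2.0 ** (-0.5 * e)
    elif label == "F":
        front["theta"] = 2.0 ** e
        front["alpha"] = 2.0 ** (-0.5 * e)
    elif label != "C":
        raise ValueError(f"unknown class {label!r}")
    return glob, front


def one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                     exponent: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    # amplitude ~ f^(-exponent/2) so power ~ f^(-exponent); flat below 0.5 Hz
    shaping[nz] = np.maximum(freqs[nz], 0.5) ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    return x / x.std()


def _oscillator(rng: np.random.Generator, n: int, fs: float, band) -> np.ndarray:
    """Amplitude- and frequency-modulated oscillation inside the band.

    The slow (~0.3 Hz) random-phase AM plus a slow wander of the
    instantaneous frequency (smoothed random walk, ~15 % of the band width)
    reproduce the non-stationarity of real rhythms: no two frames of the
    same subject show the oscillation at an identical sharp frequency.
    Mean square is normalised to 1.
    """
    from scipy.ndimage import gaussian_filter1d

    lo, hi = band
    width = hi - lo
    f0 = rng.uniform(lo + 0.2 * width, hi - 0.2 * width)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / fs
    # slow frequency wander (~1 s correlation time), synthesised on a coarse
    # 10 Hz grid and interpolated; clipped to stay inside the band
    fs_coarse = 10.0
    n_coarse = max(int(np.ceil(n / fs * fs_coarse)) + 2, 4)
    wander = gaussian_filter1d(rng.standard_normal(n_coarse), sigma=fs_coarse)
    sd = wander.std()
    if sd > 0:
        wander = wander / sd * 0.15 * width
    wander = np.interp(t, np.arange(n_coarse) / fs_coarse, wander)
    f_t = np.clip(f0 + wander, lo, hi)
    inst_phase = 2 * np.pi * np.cumsum(f_t) / fs + phase
    am_f = rng.uniform(0.1, 0.4)
    am_phase = rng.uniform(0, 2 * np.pi)
    env = 1.0 + 0.4 * np.sin(2 * np.pi * am_f * t + am_phase)
    x = env * np.sin(inst_phase)
    return x / np.sqrt(np.mean(x ** 2))


def generate_subject(spec: SyntheticSpec, class_label: str,
                     subject_seed: int) -> EEGRecording:
    """Generate one subject's 19-channel recording.

    Per subject, each band's target power is the class-adjusted mean times a
    lognormal factor exp(N(0, subject_sd)); per channel the oscillator gets
    an independent phase and a mild amplitude jitter. Signal scale is in
    microvolts (background SD 10 uV).
    """
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class {class_label!r}")
    rng = np.random.default_rng([spec.seed, int(subject_seed), CLASS_LABELS.index(class_label)])
    n = int(round(spec.duration_s * spec.fs))
    glob_mult, front_mult = class_band_multipliers(class_label, spec.effect_size)
    subj_factor = {b: float(np.exp(rng.normal(0.0, spec.subject_sd))) for b in BANDS}

    bg_sd = 10.0  # microvolts
    sig = np.empty((len(MONTAGE_19), n))
    frontal = set(FRONTAL_CHANNELS)
    for ci, ch in enumerate(MONTAGE_19):
        x = one_over_f_noise(rng, n, spec.fs, spec.noise_exponent) * bg_sd
        for b, band in BANDS.items():
            power = (spec.band_powers[b] * glob_mult[b] * subj_factor[b]
                     * (front_mult[b] if ch in frontal else 1.0))
            # oscillator power relative to background variance
            amp = bg_sd * np.sqrt(spec.osc_to_noise * power)
            jitter = np.exp(rng.normal(0.0, 0.05))
            x = x + amp * jitter * _oscillator(rng, n, spec.fs, band)
        sig[ci] = x - x.mean()
    return EEGRecording(
        subject_id=f"sub-{class_label}{int(subject_seed):03d}",
        label=class_label, fs=spec.fs, channels=MONTAGE_19, signal=sig,
    )


def generate_cohort(spec: SyntheticSpec) -> list:
    """Generate ``n_subjects_per_class`` recordings per class, seeded disjointly."""
    cohort = []
    for label in spec.classes:
        for i in range(spec.n_subjects_per_class):
            cohort.append(generate_subject(spec, label, i))
    return cohort


def write_cohort(cohort, out_dir) -> Path:
    """Write a cohort as EDF files plus a BIDS-style participants.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        write_edf(rec, out_dir / f"{rec.subject_id}.edf")
        rows.append({"subject_id": rec.subject_id, "label": rec.label})
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "participants.tsv", sep="\t", index=False)
    return out_dir


def band_power(x: np.ndarray, fs: float, band) -> float:
    """Welch-periodogram power of ``x`` integrated over ``band`` (Hz)."""
    from scipy.signal import welch

    f, p = welch(x, fs=fs, nperseg=min(len(x), int(4 * fs)))
    lo, hi = band
    sel = (f >= lo) & (f <= hi)
    return float(np.trapezoid(p[sel], f[sel]))
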