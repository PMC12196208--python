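"""EEG data model, EDF ingestion, pre-processing and frame segmentation.

The pipeline operates on 19-channel scalp EEG in the 10-20 montage. Signals
are carried as ``[n_channels x n_samples]`` float arrays in microvolts;
absolute scale is irrelevant downstream because every time-frequency image is
per-image normalised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

#: Fixed 10-20 montage order; the depth axis of every image stack follows it.
MONTAGE_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Frontal electrodes, where frontotemporal-dementia effects concentrate.
FRONTAL_CHANNELS = ("Fp1", "Fp2", "F3", "F7", "F8")

CLASS_LABELS = ("A", "F", "C")  # Alzheimer's, frontotemporal dementia, control


class MontageError(ValueError):
    """Raised when a file does not contain the expected 10-20 channels."""


@dataclass
class EEGRecording:
    """One subject's multi-channel EEG signal.

    Attributes
    ----------
    subject_id : str
    label : str
        Class label: "A" (AD), "F" (FTD), "C" (control) or "unknown".
    fs : float
        Sampling rate in Hz.
    channels : tuple of str
        Ordered channel names; rows of ``signal`` follow this order.
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    reference_pair : ndarray or None, shape (2, n_samples)
        Optional mastoid (A1, A2) signals for re-referencing.
    """

    subject_id: str
    label: str
    fs: float
    channels: tuple
    signal: np.ndarray
    reference_pair: np.ndarray | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.channels = tuple(self.channels)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D [channels x samples]")
        if self.signal.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.signal.shape[0]} signal rows but {len(self.channels)} channel names"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signal.shape[1] < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class FrameSet:
    """The fixed-length, overlapping frames cut from one recording."""

    subject_id: str
    label: str
    fs: float
    frame_length_s: float
    overlap_frac: float
    frames: list = field(default_factory=list)
    frame_index: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)


def _match_montage(file_channels):
    """Map montage names to row indices of the file channels.

    Matching is case-insensitive and tolerant of clinical prefixes/suffixes
    such as ``"EEG Fp1-Ref"``.
    """
    def norm(name):
        n = name.strip().lower()
        if n.startswith("eeg "):
            n = n[4:]
        n = n.split("-")[0].strip()
        return n

    normalized = [norm(c) for c in file_channels]
    mapping = {}
    for target in MONTAGE_19:
        t = target.lower()
        if t in normalized:
            mapping[target] = normalized.index(t)
    return mapping


def read_edf(path, participants: pd.DataFrame | str | Path | None = None) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording`.

    Channels are restricted and reordered to the 19-name 10-20 montage.
    The class label is looked up in an optional participants table
    (columns ``subject_id``, ``label``), else set to ``"unknown"``.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    mapping = _match_montage(raw.ch_names)
    missing = [c for c in MONTAGE_19 if c not in mapping]
    if missing:
        raise MontageError(
            f"EDF file {path.name} is missing {len(missing)} montage channels: "
            + ", ".join(missing)
        )
    data = raw.get_data()  # volts
    rows = [mapping[c] for c in MONTAGE_19]
    sig = data[rows] * 1e6  # -> microvolts

    ref = None
    ref_map = {}
    for ref_name in ("A1", "A2"):
        n = [c.strip().lower().replace("eeg ", "").split("-")[0] for c in raw.ch_names]
        if ref_name.lower() in n:
            ref_map[ref_name] = n.index(ref_name.lower())
    if len(ref_map) == 2:
        ref = data[[ref_map["A1"], ref_map["A2"]]] * 1e6

    subject_id = path.stem
    label = "unknown"
    if participants is not None:
        if not isinstance(participants, pd.DataFrame):
            participants = pd.read_csv(participants, sep="\t")
        hit = participants.loc[participants["subject_id"] == subject_id, "label"]
        if len(hit):
            label = str(hit.iloc[0])

    return EEGRecording(
        subject_id=subject_id,
        label=label,
        fs=float(raw.info["sfreq"]),
        channels=MONTAGE_19,
        signal=sig,
        reference_pair=ref,
    )


def write_edf(rec: EEGRecording, path, include_reference: bool = False) -> Path:
    """Write a recording as a minimal EDF file (16-bit, 1-second records).

    The recording is truncated to a whole number of seconds, as EDF stores
    fixed-duration data records.
    """
    path = Path(path)
    n_rec = int(rec.n_samples // rec.fs)
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF record (1 s)")
    spr = int(round(rec.fs))  # samples per record per channel

    channels = list(rec.channels)
    sig = rec.signal[:, : n_rec * spr]
    if include_reference and rec.reference_pair is not None:
        channels = channels + ["A1", "A2"]
        sig = np.vstack([sig, rec.reference_pair[:, : n_rec * spr]])
    ns = len(channels)

    # physical scaling per channel, symmetric around zero
    pmax = np.maximum(np.abs(sig).max(axis=1), 1e-6)
    dmax = 32767

    header = bytearray()
    header += f"{'0':<8}".encode()                     # version
    header += f"{rec.subject_id:<80.80}".encode()      # patient id
    header += f"{'eegfusion':<80.80}".encode()         # recording id
    header += b"01.01.00"                              # start date
    header += b"00.00.00"                              # start time
    header += f"{256 * (1 + ns):<8}".encode()          # header bytes
    header += b" " * 44                                # reserved
    header += f"{n_rec:<8}".encode()
    header += f"{1:<8}".encode()                       # record duration (s)
    header += f"{ns:<4}".encode()

    def fld(values, width):
        return "".join(f"{v:<{width}.{width}}" for v in values).encode()

    header += fld(channels, 16)
    header += fld(["AgAgCl electrode"] * ns, 80)
    header += fld(["uV"] * ns, 8)
    header += fld([f"{-p:.6g}"[:8] for p in pmax], 8)
    header += fld([f"{p:.6g}"[:8] for p in pmax], 8)
    header += fld([str(-dmax)] * ns, 8)
    header += fld([str(dmax)] * ns, 8)
    header += fld([""] * ns, 80)                       # prefiltering
    header += fld([str(spr)] * ns, 8)
    header += fld([""] * ns, 32)                       # reserved

    digital = np.round(sig / pmax[:, None] * dmax).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            chunk = digital[:, r * spr : (r + 1) * spr]
            fh.write(chunk.tobytes())
    return path


def bandpass_filter(rec: EEGRecording, low: float = 0.5, high: float = 45.0,
                    order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied channel-wise.

    Defaults match clinical EEG practice for dementia screening
    (0.5-45 Hz, 4th order, forward-backward).
    """
    nyq = rec.fs / 2.0
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyq:
        raise ValueError(f"high={high} Hz must be below Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=1)
    ref = rec.reference_pair
    if ref is not None:
        ref = sps.sosfiltfilt(sos, ref, axis=1)
    return replace(rec, signal=filtered, reference_pair=ref)


def rereference_average_mastoids(rec: EEGRecording) -> EEGRecording:
    """Subtract the mean of the two mastoid electrodes (A1, A2) from every channel."""
    if rec.reference_pair is None:
        raise ValueError("recording has no (A1, A2) reference pair")
    ref_mean = rec.reference_pair.mean(axis=0)
    return replace(rec, signal=rec.signal - ref_mean[None, :], reference_pair=None)


def preprocess(rec: EEGRecording, low: float = 0.5, high: float = 45.0) -> EEGRecording:
    """Standard pre-processing chain: band-pass filter, then re-reference if possible."""
    out = bandpass_filter(rec, low, high)
    if out.reference_pair is not None:
        out = rereference_average_mastoids(out)
    return out


def n_frames(n_samples: int, fs: float, frame_length_s: float = 4.0,
             overlap_frac: float = 0.5) -> int:
    """Number of full frames: floor((N - L) / H) + 1 with hop H = L*(1-overlap)."""
    L = int(round(frame_length_s * fs))
    H = int(round(frame_length_s * (1.0 - overlap_frac) * fs))
    if n_samples < L:
        return 0
    return (n_samples - L) // H + 1


def segment_frames(rec: EEGRecording, frame_length_s: float = 4.0,
                   overlap_frac: float = 0.5) -> FrameSet:
    """Cut a recording into fixed-length overlapping frames.

    Frames start at t=0 with hop ``frame_length_s * (1 - overlap_frac)``;
    trailing samples that do not fill a whole frame are dropped.
    """
    if not (0 <= overlap_frac < 1):
        raise ValueError("overlap_frac must be in [0, 1)")
    L = int(round(frame_length_s * rec.fs))
    H = int(round(frame_length_s * (1.0 - overlap_frac) * rec.fs))
    if rec.n_samples < L:
        raise ValueError(
            f"recording too short: {rec.duration_s:.2f} s < frame length {frame_length_s} s"
        )
    k = (rec.n_samples - L) // H + 1
    frames = [rec.signal[:, i * H : i * H + L].copy() for i in range(k)]
    return FrameSet(
        subject_id=rec.subject_id,
        label=rec.label,
        fs=rec.fs,
        frame_length_s=frame_length_s,
        overlap_frac=overlap_frac,
        frames=frames,
        frame_index=list(range(k)),
    )
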