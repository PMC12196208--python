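"""Compute the three time-frequency images for one EEG frame.

Takes a 4 s frame from a synthetic subject, computes the spectrogram,
scalogram and Hilbert spectrum of one channel, reports their native
shapes, and builds the full 128x128x19 grayscale stacks the classifier
consumes.
"""

import numpy as np

from eegfusion.core import segment_frames
from eegfusion.synthetic import SyntheticSpec, generate_subject
from eegfusion.timefreq import (build_stack, compute_scalogram,
                                compute_spectrogram, hilbert_spectrum)

rec = generate_subject(SyntheticSpec(duration_s=12.0, seed=0), "C", 0)
frame = segment_frames(rec).frames[0]
channel = frame[8]  # C3

S = compute_spectrogram(channel, fs=rec.fs)
W = compute_scalogram(channel, fs=rec.fs)
H = hilbert_spectrum(channel, fs=rec.fs)
print(f"spectrogram: {S.shape}  (92 band bins x 126 windows)")
print(f"scalogram:   {W.shape}  (122 scales x 2000 time points)")
print(f"hilbert:     {H.shape}  (128 frequency bins x 2000 time points)")

stack = build_stack(frame, fs=rec.fs)
for name in ("spectrogram", "scalogram", "hilbert"):
    img = getattr(stack, name)
    print(f"{name} stack: {img.shape}, values in "
          f"[{img.min():.2f}, {img.max():.2f}]")
print("each frame becomes three 128x128x19 grayscale tensors; the depth "
      "axis follows the 10-20 montage order")
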