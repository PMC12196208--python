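"""Empirical mode decomposition by sifting.

Decomposes a 1-D signal into intrinsic mode functions (IMFs) plus a residual
such that ``sum(imfs) + residual == signal`` exactly (each IMF is obtained by
subtraction, so reconstruction is conservative by construction). Envelopes
use cubic splines through the local extrema with a mirrored boundary
extension; sifting stops on a Cauchy-type criterion
``SD = sum((h_prev - h)^2) / sum(h_prev^2) <= sd_threshold``.

IMFs come out ordered from the highest-frequency oscillation to the lowest.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline


def _local_extrema(x: np.ndarray):
    """Indices of strict local maxima and minima; plateaus use their midpoint."""
    dx = np.diff(x)
    # collapse zero slopes to the sign of the next nonzero slope
    sgn = np.sign(dx)
    nz = sgn != 0
    if not nz.any():
        return np.array([], int), np.array([], int)
    # forward-fill zero signs
    idx = np.where(nz, np.arange(len(sgn)), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, sgn[np.maximum(idx, 0)], 0)
    change = np.diff(filled)
    maxima = np.where(change < 0)[0] + 1
    minima = np.where(change > 0)[0] + 1
    return maxima, minima


def _mirror_extend(x, idx, n, n_mirror=2):
    """Mirror up to `n_mirror` extrema around each end for spline stability."""
    t = idx.astype(float)
    v = x[idx]
    left_t = 2 * 0.0 - t[1 : n_mirror + 1][::-1] if len(t) > 1 else np.array([])
    left_v = v[1 : n_mirror + 1][::-1] if len(v) > 1 else np.array([])
    right_t = 2 * (n - 1.0) - t[-n_mirror - 1 : -1][::-1] if len(t) > 1 else np.array([])
    right_v = v[-n_mirror - 1 : -1][::-1] if len(v) > 1 else np.array([])
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, v, right_v])
    # guard against duplicate abscissae after mirroring
    tt, uniq = np.unique(tt, return_index=True)
    return tt, vv[uniq]


def _envelope_mean(x: np.ndarray):
    """Mean of upper and lower cubic-spline envelopes, or None if too few extrema."""
    n = len(x)
    maxima, minima = _local_extrema(x)
    if len(maxima) < 2 or len(minima) < 2:
        return None, len(maxima) + len(minima)
    t = np.arange(n, dtype=float)
    tmax, vmax = _mirror_extend(x, maxima, n)
    tmin, vmin = _mirror_extend(x, minima, n)
    upper = CubicSpline(tmax, vmax)(t)
    lower = CubicSpline(tmin, vmin)(t)
    return 0.5 * (upper + lower), len(maxima) + len(minima)


def sift(x: np.ndarray, sd_threshold: float = 0.2, max_iter: int = 50):
    """Extract one IMF from ``x``; returns None if ``x`` has too few extrema."""
    h = np.asarray(x, dtype=np.float64).copy()
    for _ in range(max_iter):
        mean, n_ext = _envelope_mean(h)
        if mean is None:
            return None
        h_new = h - mean
        denom = np.sum(h * h)
        if denom == 0:
            return None
        sd = np.sum((h - h_new) ** 2) / denom
        h = h_new
        if sd <= sd_threshold:
            break
    return h


def emd(x: np.ndarray, max_imfs: int = 10, sd_threshold: float = 0.2,
        max_siftings: int = 50):
    """Full decomposition: returns ``(imfs, residual)``.

    A constant or monotone signal yields no IMFs and ``residual == x``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("emd expects a non-empty 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")

    imfs = []
    residual = x.copy()
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residual)
        if len(maxima) + len(minima) < 4:
            break
        imf = sift(residual, sd_threshold=sd_threshold, max_iter=max_siftings)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf
    return imfs, residual
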