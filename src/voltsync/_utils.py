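"""Shared numerical helpers: edge-truncated moving statistics and interval math."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import median_filter


def moving_average_truncated(x: np.ndarray, halfwidth: int) -> np.ndarray:
    """Centered moving average with windows shrunk (not padded) at the edges.

    Window at sample i is x[max(0, i-halfwidth) : i+halfwidth+1].
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    csum = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.maximum(np.arange(n) - halfwidth, 0)
    hi = np.minimum(np.arange(n) + halfwidth + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def moving_median_truncated(x: np.ndarray, halfwidth: int) -> np.ndarray:
    """Centered moving median; edge windows shrink instead of padding.

    Interior is scipy's median_filter; the first/last `halfwidth` samples are
    recomputed on the truncated windows.
    """
    x = np.asarray(x, dtype=float)
    out = median_filter(x, size=2 * halfwidth + 1, mode="nearest")
    k = min(halfwidth, x.size)
    for i in range(k):
        out[i] = np.median(x[: i + halfwidth + 1])
        j = x.size - 1 - i
        if j >= 0:
            out[j] = np.median(x[max(0, j - halfwidth):])
    return out


def merge_boolean_runs(mask: np.ndarray) -> np.ndarray:
    """Return (n_runs, 2) array of [start, stop) index pairs of True runs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return np.empty((0, 2), dtype=int)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        stops = np.concatenate((stops, [mask.size]))
    return np.column_stack((starts, stops))


def total_interval_duration(intervals) -> float:
    return float(sum(e - s for s, e in intervals))


def in_any_interval(times: np.ndarray, intervals) -> np.ndarray:
    """Boolean mask: which times fall inside any half-open [start, end)."""
    times = np.asarray(times, dtype=float)
    mask = np.zeros(times.shape, dtype=bool)
    for s, e in intervals:
        mask |= (times >= s) & (times < e)
    return mask


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    out = np.mod(np.asarray(phi, dtype=float) + np.pi, 2.0 * np.pi) - np.pi
    if np.ndim(out) == 0:
        return np.pi if out == -np.pi else out
    out[out == -np.pi] = np.pi
    return out
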