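"""Spike cross-correlograms: grand-average and pairwise, with jitter nulls.

The grand-average CCG histograms spike-time differences between a reference
cell and all other cells of the session (1 ms bins, ±500 ms window),
normalized by the number of reference spikes times the number of other
cells.  Pairwise CCGs are kept raw; their peak (local maximum within
±30 ms) is compared with a null built by jittering the target train within
±75 ms for 1000 iterations.  Synchronization strength is the observed peak
over the mean jittered count in the same bin (≈1 under independence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import in_any_interval


class UndefinedCcgError(ValueError):
    """CCG requested for an empty reference train."""


class UndefinedFwhmError(ValueError):
    """No half-maximum crossings exist within the window."""


class PairExcludedError(ValueError):
    """Pair excluded from pairwise CCG analysis (too few counts)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class CCGResult:
    lags_ms: np.ndarray
    counts: np.ndarray               # normalized (grand) or raw (pairwise)
    peak_lag_ms: float
    peak_value: float
    fwhm_ms: float = np.nan
    p_value: float = np.nan
    sync_strength: float = np.nan
    n_pair_counts: int = 0
    state: str = "all"
    meta: dict = field(default_factory=dict)


def _restrict(train: np.ndarray, state_intervals) -> np.ndarray:
    train = np.asarray(train, dtype=float)
    if state_intervals is None:
        return train
    return train[in_any_interval(train, state_intervals)]


def _ccg_histogram(ref: np.ndarray, target: np.ndarray, window_ms: float,
                   bin_ms: float = 1.0):
    """Counts of (t_target - t_ref) in 1 ms bins centered on integer lags."""
    w = int(round(window_ms))
    lags = np.arange(-w, w + 1, int(round(bin_ms)), dtype=float)
    counts = np.zeros(lags.size)
    if ref.size == 0 or target.size == 0:
        return lags, counts
    tgt = np.sort(target)
    half_s = (window_ms + bin_ms / 2.0) / 1000.0
    lo = np.searchsorted(tgt, ref - half_s, side="left")
    hi = np.searchsorted(tgt, ref + half_s, side="right")
    total = int(np.sum(hi - lo))
    if total == 0:
        return lags, counts
    ref_rep = np.repeat(ref, hi - lo)
    take = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
    diffs_ms = (tgt[take] - ref_rep) * 1000.0
    # +1e-9 breaks boundary ties upward deterministically: grid-aligned spike
    # times put diffs exactly on half-integer bin edges, and raw float
    # rounding would otherwise split them with a systematic pattern
    idx = np.floor(diffs_ms / bin_ms + 0.5 + 1e-9).astype(int) + w
    ok = (idx >= 0) & (idx < lags.size)
    np.add.at(counts, idx[ok], 1.0)
    return lags, counts


def _peak_with_ties(lags_ms: np.ndarray, counts: np.ndarray, search_ms: float):
    """Peak within |lag| <= search_ms; ties -> smallest |lag|, then negative lag."""
    mask = np.abs(lags_ms) <= search_ms
    sub_lags, sub = lags_ms[mask], counts[mask]
    top = np.flatnonzero(sub == sub.max())
    order = sorted(top, key=lambda i: (abs(sub_lags[i]), sub_lags[i]))
    best = order[0]
    return float(sub_lags[best]), float(sub[best])


def grand_average_ccg(ref_spikes: np.ndarray, other_trains: list,
                      window_ms: float = 500.0, bin_ms: float = 1.0,
                      state_intervals=None, state: str = "all") -> CCGResult:
    """Grand-average CCG of a reference cell against the rest of the population.

    Counts are divided by (number of reference spikes x number of other
    cells).  With ``state_intervals`` given, both the reference and target
    spikes are restricted to those intervals.
    """
    ref = _restrict(ref_spikes, state_intervals)
    if ref.size == 0:
        raise UndefinedCcgError("reference train empty")
    if not other_trains:
        raise ValueError("need at least one other train")
    others = [_restrict(t, state_intervals) for t in other_trains]
    lags, counts = _ccg_histogram(ref, np.concatenate(others) if others else np.empty(0),
                                  window_ms, bin_ms)
    norm = counts / (ref.size * len(others))
    peak_lag, peak_val = _peak_with_ties(lags, norm, 30.0)
    try:
        fwhm = ccg_fwhm(lags, norm)
    except UndefinedFwhmError:
        fwhm = np.nan
    return CCGResult(lags_ms=lags, counts=norm, peak_lag_ms=peak_lag,
                     peak_value=peak_val, fwhm_ms=fwhm,
                     n_pair_counts=int(counts.sum()), state=state)


def ccg_fwhm(lags_ms: np.ndarray, counts: np.ndarray,
             baseline_lag_ms: float = 400.0) -> float:
    """Full width at half maximum of the CCG peak, above a far-lag baseline.

    Baseline = mean of bins with |lag| > 400 ms; width measured at
    baseline + (peak - baseline)/2 with linear interpolation between bins.
    """
    lags_ms = np.asarray(lags_ms, dtype=float)
    counts = np.asarray(counts, dtype=float)
    baseline = float(np.mean(counts[np.abs(lags_ms) > baseline_lag_ms])) \
        if np.any(np.abs(lags_ms) > baseline_lag_ms) else float(np.min(counts))
    peak_i = int(np.argmax(counts))
    peak = counts[peak_i]
    if peak <= np.median(counts) or peak <= baseline:
        raise UndefinedFwhmError("no peak above baseline")
    half = baseline + (peak - baseline) / 2.0
    left = np.nan
    for i in range(peak_i, 0, -1):
        if counts[i - 1] < half <= counts[i]:
            frac = (counts[i] - half) / (counts[i] - counts[i - 1])
            left = lags_ms[i] - frac * (lags_ms[i] - lags_ms[i - 1])
            break
    right = np.nan
    for i in range(peak_i, counts.size - 1):
        if counts[i + 1] < half <= counts[i]:
            frac = (counts[i] - half) / (counts[i] - counts[i + 1])
            right = lags_ms[i] + frac * (lags_ms[i + 1] - lags_ms[i])
            break
    if np.isnan(left) or np.isnan(right):
        raise UndefinedFwhmError("no half-maximum crossings within the window")
    return float(right - left)


def session_shuffle_control(ref_spikes: np.ndarray, other_sessions: dict,
                            n_cells: int, seed: int | np.random.Generator = 0,
                            window_ms: float = 500.0) -> CCGResult:
    """Grand CCG against cells drawn from *other* sessions (flat null).

    ``other_sessions`` maps session_id -> list of spike trains; the pool must
    span at least two sessions.
    """
    if len(other_sessions) < 2:
        raise ValueError("shuffle pool must span at least 2 sessions")
    pool = [t for trains in other_sessions.values() for t in trains]
    if len(pool) < n_cells:
        raise ValueError("shuffle pool smaller than requested cell count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_cells, replace=False)
    return grand_average_ccg(ref_spikes, [pool[i] for i in chosen],
                             window_ms=window_ms, state="shuffle")


def pairwise_ccg(train_a: np.ndarray, train_b: np.ndarray, duration_s: float,
                 state_intervals=None, state: str = "all",
                 n_jitters: int = 1000, jitter_halfwidth_ms: float = 75.0,
                 seed: int | np.random.Generator = 0,
                 window_ms: float = 500.0, peak_search_ms: float = 30.0,
                 min_counts: int = 100) -> CCGResult:
    """Pairwise CCG with jitter-based significance and synchronization strength.

    Raises PairExcludedError when the ±500 ms window holds no more than
    ``min_counts`` spike pairs.  p uses an add-one correction,
    (1 + #{jittered peaks >= observed}) / (1 + n_jitters).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.sort(_restrict(train_a, state_intervals))
    b = np.sort(_restrict(train_b, state_intervals))
    lags, counts = _ccg_histogram(a, b, window_ms)
    n_counts = int(counts.sum())
    if n_counts <= min_counts:
        raise PairExcludedError(
            f"only {n_counts} counts in ±{window_ms:.0f} ms (need > {min_counts})")
    peak_lag, peak_val = _peak_with_ties(lags, counts, peak_search_ms)

    # Jitter null: only diffs that can land within the peak-search window
    # after a ±75 ms displacement matter.
    w = int(round(peak_search_ms))
    nbins = 2 * w + 1
    reach_s = (peak_search_ms + 0.5 + jitter_halfwidth_ms) / 1000.0
    lo = np.searchsorted(b, a - reach_s, side="left")
    hi = np.searchsorted(b, a + reach_s, side="right")
    ref_rep = np.repeat(a, hi - lo)
    b_idx = np.concatenate([np.arange(s, e) for s, e in zip(lo, hi) if e > s]) \
        if np.any(hi > lo) else np.empty(0, dtype=int)
    diffs = b[b_idx] - ref_rep if b_idx.size else np.empty(0)
    half_s = jitter_halfwidth_ms / 1000.0
    jitter_ccgs = np.zeros((n_jitters, nbins))
    if b_idx.size:
        for k in range(n_jitters):
            delta = rng.uniform(-half_s, half_s, size=b.size)
            delta = np.clip(b + delta, 0.0, duration_s) - b
            shifted_ms = (diffs + delta[b_idx]) * 1000.0
            idx = np.floor(shifted_ms + 0.5 + 1e-9).astype(int) + w
            ok = (idx >= 0) & (idx < nbins)
            jitter_ccgs[k] = np.bincount(idx[ok], minlength=nbins)
    jitter_peaks = jitter_ccgs.max(axis=1)
    p = (1.0 + np.count_nonzero(jitter_peaks >= peak_val)) / (1.0 + n_jitters)
    peak_bin = int(round(peak_lag)) + w
    mean_at_peak = float(jitter_ccgs[:, peak_bin].mean())
    strength = peak_val / mean_at_peak if mean_at_peak > 0 else np.inf
    try:
        fwhm = ccg_fwhm(lags, counts)
    except UndefinedFwhmError:
        fwhm = np.nan
    return CCGResult(lags_ms=lags, counts=counts, peak_lag_ms=peak_lag,
                     peak_value=peak_val, fwhm_ms=fwhm, p_value=float(p),
                     sync_strength=float(strength), n_pair_counts=n_counts,
                     state=state)


def smooth_for_display(counts: np.ndarray, width: int = 5) -> np.ndarray:
    """Centered moving average for plotting only; never used in statistics."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < width:
        raise ValueError(f"need at least {width} bins")
    return np.convolve(counts, np.full(width, 1.0 / width), mode="same")
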