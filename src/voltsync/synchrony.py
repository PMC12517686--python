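"""Population-synchrony detection against jitter surrogates.

Spikes of all cells are summed in a 25 ms window sliding by one imaging
sample.  Surrogates displace every spike independently by U(-75, +75) ms,
destroying millisecond coordination while preserving per-cell rates; moments
where the observed count exceeds the surrogate mean plus four SDs are merged
into synchronous events.  Two controls are provided: removal of later spikes
in bursts, and a shuffle that randomizes the theta cycle of each spike while
preserving its theta phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import merge_boolean_runs, wrap_phase


@dataclass
class SyncEventSet:
    event_times: np.ndarray          # seconds, run midpoints, sorted
    participants: list               # per-event set of cell ids
    ensemble_size_pct: np.ndarray    # % of analyzable cells per event
    peak_counts: np.ndarray          # max observed count within each run
    threshold_at_peak: np.ndarray
    threshold_trace: np.ndarray
    surrogate_mean: np.ndarray
    surrogate_sd: np.ndarray
    n_jitters: int
    jitter_halfwidth_ms: float
    window_ms: float

    @property
    def n_events(self) -> int:
        return self.event_times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "event_time_s": self.event_times,
            "n_participants": [len(p) for p in self.participants],
            "ensemble_size_pct": self.ensemble_size_pct,
            "peak_count": self.peak_counts,
            "threshold_at_peak": self.threshold_at_peak,
        })


def _bin_spikes(spike_times: np.ndarray, n_samples: int,
                sampling_rate_hz: float) -> np.ndarray:
    idx = np.floor(np.asarray(spike_times, dtype=float) * sampling_rate_hz).astype(int)
    idx = np.clip(idx, 0, n_samples - 1)
    return np.bincount(idx, minlength=n_samples).astype(float)


def _window_sum(binned: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered sliding sum over [i - w/2, i + w/2) samples, edges truncated."""
    half = window_samples // 2
    csum = np.concatenate(([0.0], np.cumsum(binned)))
    n = binned.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + (window_samples - half), n)
    return csum[hi] - csum[lo]


def sliding_counts(spike_trains: dict[str, np.ndarray], duration_s: float,
                   sampling_rate_hz: float = 2000.0,
                   window_ms: float = 25.0) -> np.ndarray:
    """Total spike count across cells in a sliding 25 ms window, one value
    per imaging sample."""
    if not spike_trains:
        raise ValueError("need at least one cell")
    n = int(round(duration_s * sampling_rate_hz))
    w = int(round(window_ms * sampling_rate_hz / 1000.0))
    all_spikes = np.concatenate([np.asarray(t, dtype=float) for t in spike_trains.values()]) \
        if any(np.size(t) for t in spike_trains.values()) else np.empty(0)
    return _window_sum(_bin_spikes(all_spikes, n, sampling_rate_hz), w)


def jitter_surrogates(spike_trains: dict[str, np.ndarray], duration_s: float,
                      sampling_rate_hz: float = 2000.0, window_ms: float = 25.0,
                      halfwidth_ms: float = 75.0, n: int = 500,
                      seed: int | np.random.Generator = 0):
    """Per-sample mean and SD of sliding counts over ``n`` jitter surrogates.

    Each surrogate displaces every spike by an independent U(-75, +75) ms
    offset, clipped to [0, duration).  Deterministic under a fixed seed.
    """
    if n < 2:
        raise ValueError("need at least 2 surrogates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_samples = int(round(duration_s * sampling_rate_hz))
    w = int(round(window_ms * sampling_rate_hz / 1000.0))
    all_spikes = [np.asarray(t, dtype=float) for t in spike_trains.values()]
    spikes = np.concatenate(all_spikes) if all_spikes else np.empty(0)
    if spikes.size == 0:
        z = np.zeros(n_samples)
        return z, z.copy()
    half_s = halfwidth_ms / 1000.0
    acc = np.zeros(n_samples)
    acc2 = np.zeros(n_samples)
    eps = 0.5 / sampling_rate_hz
    for _ in range(n):
        jit = spikes + rng.uniform(-half_s, half_s, size=spikes.size)
        np.clip(jit, 0.0, duration_s - eps, out=jit)
        counts = _window_sum(_bin_spikes(jit, n_samples, sampling_rate_hz), w)
        acc += counts
        acc2 += counts * counts
    mean = acc / n
    var = np.maximum(acc2 / n - mean * mean, 0.0)
    return mean, np.sqrt(var)


def detect_events(counts: np.ndarray, surrogate_mean: np.ndarray,
                  surrogate_sd: np.ndarray, spike_trains: dict[str, np.ndarray],
                  sampling_rate_hz: float = 2000.0, window_ms: float = 25.0,
                  k_sd: float = 4.0, n_jitters: int = 500,
                  jitter_halfwidth_ms: float = 75.0,
                  n_analyzable: int | None = None) -> SyncEventSet:
    """Merge supra-threshold runs of the count trace into synchronous events.

    The threshold is surrogate mean + ``k_sd`` SDs; a zero-SD sample with a
    positive count still triggers when the count exceeds the mean.  Event
    time is the midpoint of the run; participants are cells with at least
    one spike within ±window/2 of that time.
    """
    counts = np.asarray(counts, dtype=float)
    if not (counts.shape == np.shape(surrogate_mean) == np.shape(surrogate_sd)):
        raise ValueError("counts and surrogate series must share one length")
    threshold = np.asarray(surrogate_mean) + k_sd * np.asarray(surrogate_sd)
    runs = merge_boolean_runs(counts > threshold)
    half_w = window_ms / 2000.0
    n_cells = n_analyzable if n_analyzable is not None else len(spike_trains)
    sorted_trains = {cid: np.sort(np.asarray(t, dtype=float))
                     for cid, t in spike_trains.items()}
    times, parts, sizes, peaks, thr_at = [], [], [], [], []
    for s, e in runs:
        mid = (s + e) / 2.0 / sampling_rate_hz
        peak_i = s + int(np.argmax(counts[s:e]))
        members = {cid for cid, t in sorted_trains.items()
                   if np.searchsorted(t, mid + half_w, side="right")
                   > np.searchsorted(t, mid - half_w, side="left")}
        times.append(mid)
        parts.append(members)
        sizes.append(100.0 * len(members) / n_cells)
        peaks.append(counts[peak_i])
        thr_at.append(threshold[peak_i])
    return SyncEventSet(
        event_times=np.asarray(times), participants=parts,
        ensemble_size_pct=np.asarray(sizes), peak_counts=np.asarray(peaks),
        threshold_at_peak=np.asarray(thr_at), threshold_trace=threshold,
        surrogate_mean=np.asarray(surrogate_mean),
        surrogate_sd=np.asarray(surrogate_sd),
        n_jitters=n_jitters, jitter_halfwidth_ms=jitter_halfwidth_ms,
        window_ms=window_ms,
    )


def detect_population_synchrony(spike_trains: dict[str, np.ndarray],
                                duration_s: float,
                                sampling_rate_hz: float = 2000.0,
                                window_ms: float = 25.0,
                                jitter_halfwidth_ms: float = 75.0,
                                n_jitters: int = 500, k_sd: float = 4.0,
                                seed: int = 0,
                                n_analyzable: int | None = None) -> SyncEventSet:
    """Convenience wrapper: sliding counts + surrogates + event detection."""
    counts = sliding_counts(spike_trains, duration_s, sampling_rate_hz, window_ms)
    mean, sd = jitter_surrogates(spike_trains, duration_s, sampling_rate_hz,
                                 window_ms, jitter_halfwidth_ms, n_jitters, seed)
    return detect_events(counts, mean, sd, spike_trains, sampling_rate_hz,
                         window_ms, k_sd, n_jitters, jitter_halfwidth_ms,
                         n_analyzable)


def event_rate_segments(events: SyncEventSet, duration_s: float,
                        n_segments: int = 2) -> np.ndarray:
    """Event rate (Hz) per equal-length segment of the recording."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    seg_len = duration_s / n_segments
    idx = np.minimum((events.event_times / seg_len).astype(int), n_segments - 1)
    counts = np.bincount(idx, minlength=n_segments)
    return counts / seg_len


def remove_burst_spikes(spike_times: np.ndarray, isi_max_ms: float = 10.0) -> np.ndarray:
    """Keep burst-initiating spikes only: a spike survives when its preceding
    inter-spike interval exceeds ``isi_max_ms`` or it is the first of the train."""
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        return t.copy()
    keep = np.concatenate(([True], np.diff(t) > isi_max_ms / 1000.0))
    return t[keep]


def theta_cycle_boundaries(theta_phase: np.ndarray) -> np.ndarray:
    """Sample indices of ascending zero-phase crossings (cycle starts)."""
    phi = np.asarray(theta_phase, dtype=float)
    prev, cur = phi[:-1], phi[1:]
    cross = (prev < 0) & (cur >= 0) & (cur - prev < np.pi)
    return np.flatnonzero(cross) + 1


def theta_cycle_shuffle(spike_times: np.ndarray, theta_phase: np.ndarray,
                        sampling_rate_hz: float,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Randomize each spike's theta cycle while preserving its theta phase.

    Cycles are delimited by ascending zero-phase crossings; each spike is
    assigned a uniformly drawn cycle (with replacement) and re-placed at the
    time within that cycle corresponding to its phase under a linear
    phase-to-time inversion.  Cycles with non-monotone phase are excluded
    from the draw.  Spikes outside any complete cycle are left in place.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.asarray(spike_times, dtype=float)
    phi = np.asarray(theta_phase, dtype=float)
    bounds = theta_cycle_boundaries(phi)
    if bounds.size < 2:
        return np.sort(t.copy())
    valid = []
    for k in range(bounds.size - 1):
        seg = np.unwrap(phi[bounds[k]:bounds[k + 1]])
        if np.all(np.diff(seg) >= 0):
            valid.append((bounds[k], bounds[k + 1]))
    if not valid:
        return np.sort(t.copy())
    valid = np.asarray(valid)
    out = t.copy()
    idx = np.round(t * sampling_rate_hz).astype(int)
    idx = np.clip(idx, 0, phi.size - 1)
    inside = (idx >= bounds[0]) & (idx < bounds[-1])
    which = rng.integers(0, valid.shape[0], size=int(inside.sum()))
    phase_frac = np.mod(phi[idx[inside]], 2.0 * np.pi) / (2.0 * np.pi)
    starts = valid[which, 0] / sampling_rate_hz
    lens = (valid[which, 1] - valid[which, 0]) / sampling_rate_hz
    out[inside] = starts + phase_frac * lens
    return np.sort(out)
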