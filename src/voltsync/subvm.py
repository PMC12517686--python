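"""Subthreshold membrane-voltage (subVm) dynamics around synchrony and spikes.

subVm traces are analyzed in 1 s segments with 50% overlap; a segment is
labeled immobility (locomotion) when speed stays below 1 cm/s (above
3 cm/s) for more than 90% of its samples, otherwise it is excluded.
Pairwise cross-correlation is Pearson-style (per-segment z-scored); theta
coherence is the magnitude-squared coherence averaged over 4-12 Hz,
estimated per segment by Welch's method with 0.5 s Hann windows at 50%
overlap (a single-window estimate on one segment is degenerate == 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .lfp import PhaseSeries, ThetaModulation, vector_modulation

SEGMENT_LEN_S = 1.0
SEGMENT_STEP_S = 0.5
STATE_FRACTION = 0.9


@dataclass
class SegmentSet:
    starts_s: np.ndarray
    labels: list                    # "immobility" | "locomotion" | "excluded"
    length_s: float = SEGMENT_LEN_S
    sampling_rate_hz: float = 2000.0

    def indices(self, state: str) -> np.ndarray:
        return np.asarray([i for i, s in enumerate(self.labels) if s == state], dtype=int)


def label_segments(speed_cm_s: np.ndarray, sampling_rate_hz: float,
                   loco_thr: float = 3.0, immo_thr: float = 1.0) -> SegmentSet:
    """Slice the session into 1 s half-overlapping segments and label each
    by the 90% speed rule."""
    speed = np.asarray(speed_cm_s, dtype=float)
    seg_len = int(round(SEGMENT_LEN_S * sampling_rate_hz))
    step = int(round(SEGMENT_STEP_S * sampling_rate_hz))
    starts, labels = [], []
    for s0 in range(0, speed.size - seg_len + 1, step):
        seg = speed[s0:s0 + seg_len]
        if np.mean(seg < immo_thr) > STATE_FRACTION:
            lab = "immobility"
        elif np.mean(seg > loco_thr) > STATE_FRACTION:
            lab = "locomotion"
        else:
            lab = "excluded"
        starts.append(s0 / sampling_rate_hz)
        labels.append(lab)
    return SegmentSet(starts_s=np.asarray(starts), labels=labels,
                      sampling_rate_hz=sampling_rate_hz)


def synchrony_triggered_subvm(subvm_by_cell: dict, spike_trains: dict,
                              event_times: np.ndarray, sampling_rate_hz: float,
                              halfwidth_s: float = 0.3):
    """Mean subVm around synchrony times, per cell and across cells.

    A cell's aligned segment is discarded when that cell fired any spike
    inside the ±300 ms window; cells with no surviving segment are omitted
    from the grand mean.  Returns (per_cell_mean dict, grand_mean,
    omitted_cell_ids).
    """
    events = np.asarray(event_times, dtype=float)
    if events.size == 0:
        raise ValueError("need at least one event")
    half = int(round(halfwidth_s * sampling_rate_hz))
    per_cell, omitted = {}, []
    for cid, subvm in subvm_by_cell.items():
        spikes = np.sort(np.asarray(spike_trains.get(cid, np.empty(0)), dtype=float))
        centers = np.round(events * sampling_rate_hz).astype(int)
        ok = (centers >= half) & (centers < subvm.size - half)
        segs = []
        for c in centers[ok]:
            t0, t1 = (c - half) / sampling_rate_hz, (c + half + 1) / sampling_rate_hz
            if np.searchsorted(spikes, t1) > np.searchsorted(spikes, t0):
                continue
            segs.append(subvm[c - half:c + half + 1])
        if segs:
            per_cell[cid] = np.mean(segs, axis=0)
        else:
            omitted.append(cid)
    if not per_cell:
        raise ValueError("no cell has spike-free aligned segments")
    grand = np.mean(list(per_cell.values()), axis=0)
    return per_cell, grand, omitted


def _uniform_times_in_intervals(rng: np.random.Generator, n: int, intervals):
    lens = np.asarray([e - s for s, e in intervals], dtype=float)
    starts = np.asarray([s for s, _ in intervals], dtype=float)
    which = rng.choice(lens.size, size=n, p=lens / lens.sum())
    return starts[which] + rng.uniform(0.0, 1.0, size=n) * lens[which]


def spike_phase_modulation(categories: dict, ps: PhaseSeries,
                           state_intervals_by_category: dict,
                           n_shuffles: int = 1000,
                           seed: int | np.random.Generator = 0) -> dict:
    """Amplitude-weighted phase locking of spikes per category.

    ``categories`` maps name -> spike times; the shuffle redraws the same
    number of times uniformly inside that category's state intervals.
    Categories with zero spikes are skipped.  Returns name -> ThetaModulation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for name, spikes in categories.items():
        spikes = np.asarray(spikes, dtype=float)
        if spikes.size == 0:
            continue
        phi, amp = ps.at_times(spikes)
        strength, preferred = vector_modulation(phi, amp)
        intervals = state_intervals_by_category[name]
        count = 0
        for _ in range(n_shuffles):
            t = _uniform_times_in_intervals(rng, spikes.size, intervals)
            sphi, samp = ps.at_times(t)
            s, _ = vector_modulation(sphi, samp)
            if s >= strength:
                count += 1
        out[name] = ThetaModulation(strength=strength, preferred_phase=preferred,
                                    p_value=count / n_shuffles,
                                    n_events=spikes.size)
    return out


def spike_triggered_subvm(subvm: np.ndarray, spike_times_by_category: dict,
                          sampling_rate_hz: float, halfwidth_s: float = 0.3,
                          min_triggers: int = 5) -> dict:
    """Mean subVm segment around spikes, per category.

    Categories with fewer than ``min_triggers`` usable triggers are excluded;
    raises when every category is excluded.
    """
    subvm = np.asarray(subvm, dtype=float)
    half = int(round(halfwidth_s * sampling_rate_hz))
    out = {}
    for name, spikes in spike_times_by_category.items():
        centers = np.round(np.asarray(spikes, dtype=float) * sampling_rate_hz).astype(int)
        centers = centers[(centers >= half) & (centers < subvm.size - half)]
        if centers.size < min_triggers:
            continue
        out[name] = subvm[centers[:, None] + np.arange(-half, half + 1)].mean(axis=0)
    if not out:
        raise ValueError("all categories excluded (too few triggers)")
    return out


def _cooccurring_segments(seg: SegmentSet, state: str, n_samples: int):
    seg_len = int(round(seg.length_s * seg.sampling_rate_hz))
    for i in seg.indices(state):
        s0 = int(round(seg.starts_s[i] * seg.sampling_rate_hz))
        if s0 + seg_len <= n_samples:
            yield s0, s0 + seg_len


def pairwise_subvm_xcorr(subvm_a: np.ndarray, subvm_b: np.ndarray,
                         segments: SegmentSet, max_lag_s: float = 0.5):
    """State-averaged normalized cross-correlation of two subVm traces.

    Each co-occurring segment is z-scored before correlation; positive lag
    means cell b lags cell a.  Returns (lags_s, {state: mean_xcorr},
    {state: n_segments}).
    """
    a = np.asarray(subvm_a, dtype=float)
    b = np.asarray(subvm_b, dtype=float)
    fs = segments.sampling_rate_hz
    seg_len = int(round(segments.length_s * fs))
    max_lag = int(round(max_lag_s * fs))
    full_lags = sps.correlation_lags(seg_len, seg_len)
    keep = np.abs(full_lags) <= max_lag
    lags_s = full_lags[keep] / fs
    curves, counts = {}, {}
    for state in ("immobility", "locomotion"):
        acc = []
        for s0, s1 in _cooccurring_segments(segments, state, min(a.size, b.size)):
            sa, sb = a[s0:s1], b[s0:s1]
            if np.std(sa) == 0 or np.std(sb) == 0:
                continue
            za = (sa - sa.mean()) / sa.std()
            zb = (sb - sb.mean()) / sb.std()
            acc.append(sps.correlate(zb, za, mode="full")[keep] / seg_len)
        if acc:
            curves[state] = np.mean(acc, axis=0)
            counts[state] = len(acc)
    return lags_s, curves, counts


def pairwise_theta_coherence(subvm_a: np.ndarray, subvm_b: np.ndarray,
                             segments: SegmentSet,
                             theta_band_hz=(4.0, 12.0)):
    """State-averaged magnitude-squared theta coherence of two subVm traces.

    Per segment, Welch coherence with 0.5 s Hann windows and 50% overlap,
    averaged over 4-12 Hz; segment values are then averaged within state.
    Returns ({state: mean_coherence}, {state: n_segments},
    {state: low_confidence_flag}).
    """
    a = np.asarray(subvm_a, dtype=float)
    b = np.asarray(subvm_b, dtype=float)
    fs = segments.sampling_rate_hz
    nperseg = int(round(fs / 2.0))
    values, counts, flags = {}, {}, {}
    for state in ("immobility", "locomotion"):
        acc = []
        for s0, s1 in _cooccurring_segments(segments, state, min(a.size, b.size)):
            sa, sb = a[s0:s1], b[s0:s1]
            if np.std(sa) == 0 or np.std(sb) == 0:
                continue
            f, cxy = sps.coherence(sa, sb, fs=fs, window="hann",
                                   nperseg=nperseg, noverlap=nperseg // 2)
            band = (f >= theta_band_hz[0]) & (f <= theta_band_hz[1])
            acc.append(float(np.mean(cxy[band])))
        if acc:
            values[state] = float(np.mean(acc))
            counts[state] = len(acc)
            flags[state] = len(acc) < 2
    return values, counts, flags


def coherence_vs_distance(pair_coherences, centroid_distances_um):
    """Spearman rank correlation between pair coherence and soma distance."""
    coh = np.asarray(pair_coherences, dtype=float)
    dist = np.asarray(centroid_distances_um, dtype=float)
    if coh.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(coh) == 0 or np.ptp(dist) == 0:
        raise ValueError("ties-only input; correlation undefined")
    rho, p = stats.spearmanr(coh, dist)
    return float(rho), float(p)
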