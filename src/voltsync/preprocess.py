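"""Fluorescence preprocessing and spike detection for voltage imaging.

The sensor is negative-going: an action potential is a transient *dip* in
raw fluorescence.  Baseline (F0) is a ±0.5 s moving average, and
dF/F = (F0 - F) / F0, which makes spikes positive.  Spikes are detected on
a median high-passed residual against an amplitude threshold that minimizes
the estimated sum of type-I and type-II errors between the candidate-transient
amplitude distribution and a noise distribution built from local maxima of
the inverted residual.  Events smaller than half the mean of the top-5% kept
amplitudes are then discarded.  The subthreshold membrane-voltage proxy
(subVm) is the slow component with suprathreshold excursions linearly
interpolated away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ._utils import moving_average_truncated, moving_median_truncated


class DegenerateBaselineError(ValueError):
    """F0 is nonpositive somewhere; dF/F is undefined."""


class DegenerateNoiseError(ValueError):
    """Residual has zero variance; no noise distribution exists."""


class UndefinedSnrError(ValueError):
    """SNR requested for a cell with no detected spikes."""


@dataclass
class CellActivity:
    """Per-cell derived signals and quality metrics."""
    cell_id: str
    dff: np.ndarray
    hp_residual: np.ndarray
    spike_times: np.ndarray          # seconds, sorted
    spike_amplitudes: np.ndarray     # dF/F units, positive
    detection_threshold: float
    spike_threshold_v: float         # dF/F value at spike initiation (nan if no spikes)
    snr: float
    subvm: np.ndarray
    mean_rate_hz: float
    waveform_fwhm_ms: float
    sampling_rate_hz: float
    qc_flags: dict = field(default_factory=dict)
    qc_pass: bool = False


def compute_dff(raw_f: np.ndarray, sampling_rate_hz: float,
                baseline_halfwidth_s: float = 0.5) -> np.ndarray:
    """dF/F with a ±0.5 s moving-average baseline (edge windows shrink).

    Sign convention: dff = (F0 - F)/F0, so the negative-going sensor yields
    positive spike transients.
    """
    raw_f = np.asarray(raw_f, dtype=float)
    half = int(round(baseline_halfwidth_s * sampling_rate_hz))
    if raw_f.size <= 2 * half:
        raise ValueError("trace shorter than twice the baseline window")
    f0 = moving_average_truncated(raw_f, half)
    if np.any(f0 <= 0):
        raise DegenerateBaselineError("baseline F0 nonpositive; cannot form dF/F")
    return (f0 - raw_f) / f0


def highpass_residual(dff: np.ndarray, sampling_rate_hz: float,
                      median_window_ms: float = 5.0) -> np.ndarray:
    """dff minus its running median (default 5 ms window, shrunken edges)."""
    dff = np.asarray(dff, dtype=float)
    half = max(1, int(round(median_window_ms * sampling_rate_hz / 1000.0 / 2.0)))
    if 2 * half + 1 < 3:
        raise ValueError("median window below 3 samples")
    return dff - moving_median_truncated(dff, half)


def _error_minimizing_threshold(candidate_amps: np.ndarray,
                                noise_amps: np.ndarray) -> float:
    """Threshold minimizing [P(noise >= theta) + P(candidate < theta)].

    Evaluated on the pooled grid of observed amplitudes; ties resolved to the
    smallest threshold.
    """
    grid = np.unique(np.concatenate((candidate_amps, noise_amps)))
    noise_sorted = np.sort(noise_amps)
    cand_sorted = np.sort(candidate_amps)
    frac_noise_ge = 1.0 - np.searchsorted(noise_sorted, grid, side="left") / noise_sorted.size
    frac_cand_lt = np.searchsorted(cand_sorted, grid, side="left") / cand_sorted.size
    total = frac_noise_ge + frac_cand_lt
    return float(grid[np.argmin(total)])


def _parabolic_refine(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sub-sample peak positions by 3-point parabolic interpolation."""
    pos = idx.astype(float)
    interior = (idx > 0) & (idx < x.size - 1)
    i = idx[interior]
    a, b, c = x[i - 1], x[i], x[i + 1]
    denom = a - 2.0 * b + c
    delta = np.zeros(i.size)
    ok = denom < 0
    delta[ok] = 0.5 * (a[ok] - c[ok]) / denom[ok]
    pos[interior] = i + np.clip(delta, -0.5, 0.5)
    return pos


def detect_spikes(residual: np.ndarray, sampling_rate_hz: float,
                  top_fraction: float = 0.05,
                  amp_rule_factor: float = 0.5,
                  noise_quantile_floor: float = 0.999):
    """Detect spikes on the high-passed residual.

    Returns (spike_times_s, spike_amplitudes, detection_threshold).  Candidate
    transients are local maxima of the residual; the noise amplitude
    distribution is built from local maxima of the inverted residual; the
    detection threshold minimizes the summed type-I/type-II error estimate;
    finally events with amplitude below ``amp_rule_factor`` times the mean of
    the top ``top_fraction`` kept amplitudes are dropped.

    The threshold is floored at the ``noise_quantile_floor`` quantile of the
    noise amplitudes: when a trace holds no true spike population the error
    objective is flat up to sampling noise and its argmin is unstable, so
    without the floor the detector would pass large numbers of noise maxima.
    """
    residual = np.asarray(residual, dtype=float)
    if residual.size < int(sampling_rate_hz):
        raise ValueError("residual shorter than 1 s")
    if np.ptp(residual) == 0:
        raise DegenerateNoiseError("residual has zero variance")
    cand_idx, _ = find_peaks(residual)
    noise_idx, _ = find_peaks(-residual)
    if cand_idx.size == 0 or noise_idx.size == 0:
        return (np.empty(0), np.empty(0), np.inf)
    cand_amps = residual[cand_idx]
    noise_amps = -residual[noise_idx]
    theta = _error_minimizing_threshold(cand_amps, noise_amps)
    theta = max(theta, float(np.quantile(noise_amps, noise_quantile_floor))
                if noise_quantile_floor < 1.0 else float(noise_amps.max()))
    keep = cand_amps >= theta
    idx, amps = cand_idx[keep], cand_amps[keep]
    if idx.size:
        n_top = max(1, int(np.ceil(top_fraction * idx.size)))
        top_mean = np.mean(np.sort(amps)[-n_top:])
        keep2 = amps >= amp_rule_factor * top_mean
        idx, amps = idx[keep2], amps[keep2]
    times = _parabolic_refine(residual, idx) / sampling_rate_hz
    order = np.argsort(times)
    return times[order], amps[order], theta


def compute_snr(residual: np.ndarray, spike_times: np.ndarray,
                spike_amplitudes: np.ndarray, sampling_rate_hz: float,
                pre_ms: float = 2.0, post_ms: float = 4.0) -> float:
    """Mean spike amplitude over the SD of the spike-excised residual.

    Samples within [t - 2 ms, t + 4 ms] of every spike are deleted before the
    SD is taken.
    """
    if np.size(spike_times) == 0:
        raise UndefinedSnrError("SNR undefined without spikes")
    residual = np.asarray(residual, dtype=float)
    keep = np.ones(residual.size, dtype=bool)
    pre = int(round(pre_ms * sampling_rate_hz / 1000.0))
    post = int(round(post_ms * sampling_rate_hz / 1000.0))
    centers = np.round(np.asarray(spike_times) * sampling_rate_hz).astype(int)
    for c in centers:
        keep[max(0, c - pre): c + post + 1] = False
    sd = float(np.std(residual[keep]))
    return float(np.mean(spike_amplitudes)) / sd


def spike_waveform(residual: np.ndarray, spike_times: np.ndarray,
                   sampling_rate_hz: float, halfwidth_ms: float = 5.0) -> np.ndarray:
    """Spike-triggered mean of the residual in a ±5 ms window."""
    half = int(round(halfwidth_ms * sampling_rate_hz / 1000.0))
    centers = np.round(np.asarray(spike_times) * sampling_rate_hz).astype(int)
    centers = centers[(centers >= half) & (centers < residual.size - half)]
    if centers.size == 0:
        return np.full(2 * half + 1, np.nan)
    segs = residual[centers[:, None] + np.arange(-half, half + 1)]
    return segs.mean(axis=0)


def waveform_fwhm_ms(waveform: np.ndarray, sampling_rate_hz: float) -> float:
    """FWHM of a mean spike waveform, linear interpolation at the crossings."""
    if not np.all(np.isfinite(waveform)):
        return np.nan
    peak_i = int(np.argmax(waveform))
    half_level = waveform[peak_i] / 2.0
    left = np.nan
    for i in range(peak_i, 0, -1):
        if waveform[i - 1] < half_level <= waveform[i]:
            frac = (waveform[i] - half_level) / (waveform[i] - waveform[i - 1])
            left = i - frac
            break
    right = np.nan
    for i in range(peak_i, waveform.size - 1):
        if waveform[i + 1] < half_level <= waveform[i]:
            frac = (waveform[i] - half_level) / (waveform[i] - waveform[i + 1])
            right = i + frac
            break
    if np.isnan(left) or np.isnan(right):
        return np.nan
    return (right - left) * 1000.0 / sampling_rate_hz


def extract_subvm(dff: np.ndarray, residual: np.ndarray, spike_times: np.ndarray,
                  sampling_rate_hz: float):
    """SubVm: slow trace (dff - residual) with suprathreshold samples
    linearly interpolated.

    The spike threshold is the value of the mean spike-aligned dF/F waveform
    at the time of the peak of its first derivative (spike initiation).
    Returns (subvm, spike_threshold_v).  With no spikes the slow trace is
    returned unchanged with a NaN threshold.
    """
    dff = np.asarray(dff, dtype=float)
    slow = dff - np.asarray(residual, dtype=float)
    if np.size(spike_times) == 0:
        return slow, float("nan")
    wf = spike_waveform(dff, spike_times, sampling_rate_hz)
    if not np.all(np.isfinite(wf)):
        return slow, float("nan")
    deriv = np.gradient(wf)
    peak_i = int(np.argmax(wf))
    rise = deriv[: peak_i + 1]
    thr_i = int(np.argmax(rise)) if rise.size else int(np.argmax(deriv))
    threshold = float(wf[thr_i])
    subvm = slow.copy()
    above = subvm > threshold
    if above.all():
        warnings.warn("all subVm samples above spike threshold; trace degenerate",
                      RuntimeWarning)
        subvm[:] = threshold
        return subvm, threshold
    idx = np.arange(subvm.size)
    subvm[above] = np.interp(idx[above], idx[~above], subvm[~above])
    return subvm, threshold


def process_cell(cell_id: str, raw_f: np.ndarray, sampling_rate_hz: float,
                 duration_s: float | None = None,
                 min_snr_for_subvm: float = 5.0) -> CellActivity:
    """Run the full per-cell chain: dF/F, residual, spikes, SNR, subVm.

    Suprathreshold interpolation of the subVm needs a trustworthy spike
    waveform; for cells below the SNR inclusion criterion (which the QC step
    would exclude anyway) the detected events are treated as noise and the
    slow trace is kept unclipped.
    """
    dff = compute_dff(raw_f, sampling_rate_hz)
    residual = highpass_residual(dff, sampling_rate_hz)
    spike_times, amps, theta = detect_spikes(residual, sampling_rate_hz)
    if duration_s is None:
        duration_s = raw_f.size / sampling_rate_hz
    if spike_times.size:
        snr = compute_snr(residual, spike_times, amps, sampling_rate_hz)
        fwhm = waveform_fwhm_ms(spike_waveform(residual, spike_times, sampling_rate_hz),
                                sampling_rate_hz)
    else:
        snr, fwhm = 0.0, np.nan
    subvm_spikes = spike_times if snr >= min_snr_for_subvm else np.empty(0)
    subvm, thr_v = extract_subvm(dff, residual, subvm_spikes, sampling_rate_hz)
    return CellActivity(
        cell_id=cell_id, dff=dff, hp_residual=residual,
        spike_times=spike_times, spike_amplitudes=amps,
        detection_threshold=theta, spike_threshold_v=thr_v,
        snr=snr, subvm=subvm,
        mean_rate_hz=spike_times.size / duration_s,
        waveform_fwhm_ms=fwhm, sampling_rate_hz=sampling_rate_hz,
    )


def qc_cells(activities: list[CellActivity], centroids: dict[str, np.ndarray],
             duration_s: float,
             min_snr: float = 5.0, min_fwhm_ms: float = 0.8,
             min_rate_hz: float = 0.1, min_pair_dist_um: float = 70.0,
             min_cells: int = 9):
    """Apply the per-cell inclusion criteria and the pair-distance rule.

    A cell passes when SNR > 5, spike-waveform FWHM > 0.8 ms and mean rate
    > 0.1 Hz; among survivors closer than 70 um the lower-SNR member is
    dropped greedily.  Returns (included_ids, session_analyzable) and fills
    each activity's qc_flags.  The session is analyzable when at least
    ``min_cells`` cells survive.
    """
    if not activities:
        raise ValueError("no activities given")
    survivors = []
    for a in activities:
        flags = {
            "snr": a.snr > min_snr,
            "fwhm": np.isfinite(a.waveform_fwhm_ms) and a.waveform_fwhm_ms > min_fwhm_ms,
            "rate": a.mean_rate_hz > min_rate_hz,
            "distance": True,
        }
        a.qc_flags = flags
        if flags["snr"] and flags["fwhm"] and flags["rate"]:
            survivors.append(a)
    # greedy pair-distance exclusion: repeatedly drop the lower-SNR member of
    # the closest offending pair
    while True:
        worst = None
        for i in range(len(survivors)):
            for j in range(i + 1, len(survivors)):
                d = float(np.linalg.norm(
                    np.asarray(centroids[survivors[i].cell_id])
                    - np.asarray(centroids[survivors[j].cell_id])))
                if d < min_pair_dist_um and (worst is None or d < worst[0]):
                    worst = (d, i, j)
        if worst is None:
            break
        _, i, j = worst
        drop = i if survivors[i].snr <= survivors[j].snr else j
        survivors[drop].qc_flags["distance"] = False
        survivors.pop(drop)
    included = {a.cell_id for a in survivors}
    for a in activities:
        a.qc_pass = a.cell_id in included
    return included, len(included) >= min_cells


def qc_report(activities: list[CellActivity], centroids: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-cell QC table (cell_id, snr, fwhm_ms, mean_rate_hz, min_pair_dist_um, qc_pass)."""
    rows = []
    ids = [a.cell_id for a in activities]
    for a in activities:
        dists = [float(np.linalg.norm(np.asarray(centroids[a.cell_id])
                                      - np.asarray(centroids[o])))
                 for o in ids if o != a.cell_id]
        rows.append({
            "cell_id": a.cell_id, "snr": a.snr, "fwhm_ms": a.waveform_fwhm_ms,
            "mean_rate_hz": a.mean_rate_hz,
            "min_pair_dist_um": min(dists) if dists else np.nan,
            "qc_pass": a.qc_pass,
        })
    return pd.DataFrame(rows)


def spike_table(activities: list[CellActivity]) -> pd.DataFrame:
    """Long-format spike export (cell_id, spike_time_s, amplitude)."""
    frames = [pd.DataFrame({"cell_id": a.cell_id, "spike_time_s": a.spike_times,
                            "amplitude": a.spike_amplitudes}) for a in activities]
    if not frames:
        return pd.DataFrame(columns=["cell_id", "spike_time_s", "amplitude"])
    return pd.concat(frames, ignore_index=True)
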