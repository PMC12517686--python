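"""Behavioral state segmentation and state-conditioned firing statistics.

Locomotion is speed > 3 cm/s, immobility is speed < 1 cm/s, anything in
between is unclassified.  Labels are per-sample and merged into maximal
half-open intervals; no hysteresis or minimum duration is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import merge_boolean_runs, in_any_interval, total_interval_duration

LOCOMOTION_THRESHOLD_CM_S = 3.0
IMMOBILITY_THRESHOLD_CM_S = 1.0


@dataclass
class StateIntervals:
    locomotion: list          # [start_s, end_s) pairs
    immobility: list
    unclassified: list
    sampling_rate_hz: float

    def duration(self, state: str) -> float:
        return total_interval_duration(getattr(self, state))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"state": s, "start_s": a, "end_s": b}
                for s in ("locomotion", "immobility", "unclassified")
                for a, b in getattr(self, s)]
        return pd.DataFrame(rows, columns=["state", "start_s", "end_s"]
                            ).sort_values("start_s", ignore_index=True)


def classify_states(speed_cm_s: np.ndarray, sampling_rate_hz: float) -> StateIntervals:
    """Threshold per-sample speed into locomotion/immobility/unclassified intervals."""
    speed = np.asarray(speed_cm_s, dtype=float)
    if np.any(speed < 0) or not np.all(np.isfinite(speed)):
        raise ValueError("speed must be nonnegative and finite")
    loco = speed > LOCOMOTION_THRESHOLD_CM_S
    immo = speed < IMMOBILITY_THRESHOLD_CM_S
    other = ~(loco | immo)
    fs = float(sampling_rate_hz)

    def runs(mask):
        return [(s / fs, e / fs) for s, e in merge_boolean_runs(mask)]

    return StateIntervals(runs(loco), runs(immo), runs(other), fs)


def state_rates(spike_times: np.ndarray, intervals: StateIntervals):
    """Mean firing rate (Hz) during locomotion and immobility.

    A state with zero total duration gets rate None (undefined, flagged
    rather than NaN-propagated).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    out = []
    for state in ("locomotion", "immobility"):
        ivs = getattr(intervals, state)
        dur = total_interval_duration(ivs)
        if dur == 0:
            out.append(None)
        else:
            out.append(float(np.count_nonzero(in_any_interval(spike_times, ivs))) / dur)
    return tuple(out)


def instantaneous_rate(spike_times: np.ndarray, n_samples: int,
                       sampling_rate_hz: float, kernel_fwhm_ms: float = 250.0) -> np.ndarray:
    """Spike train convolved with a unit-area Gaussian (FWHM 250 ms), in Hz."""
    fs = float(sampling_rate_hz)
    train = np.zeros(n_samples)
    idx = np.round(np.asarray(spike_times, dtype=float) * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n_samples)]
    np.add.at(train, idx, fs)  # delta of area 1 at sample resolution
    sigma = kernel_fwhm_ms / 1000.0 * fs / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = int(np.ceil(4 * sigma))
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    return np.convolve(train, kernel, mode="same")


def rate_speed_correlation(spike_times: np.ndarray, speed_cm_s: np.ndarray,
                           sampling_rate_hz: float,
                           kernel_fwhm_ms: float = 250.0) -> float:
    """Pearson r between the Gaussian-smoothed instantaneous rate and speed."""
    speed = np.asarray(speed_cm_s, dtype=float)
    if np.size(spike_times) < 2:
        raise ValueError("need at least 2 spikes")
    if np.ptp(speed) == 0:
        raise ValueError("speed has zero variance; correlation undefined")
    rate = instantaneous_rate(spike_times, speed.size, sampling_rate_hz, kernel_fwhm_ms)
    r, _ = stats.pearsonr(rate, speed)
    return float(r)
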