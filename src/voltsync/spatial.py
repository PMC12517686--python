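"""Place-field analysis: spatial tuning curves, circular-variance selectivity,
place-cell classification, tuning similarity, and synchrony-vs-tuning.

The 90 cm one-way track is split into 36 bins of 2.5 cm.  Rates are
occupancy-normalized using only samples (and spikes) at speed > 3 cm/s.
Selectivity is 1 minus the circular variance of the tuning curve after
mapping bins onto the circle; place cells are curves with selectivity > 0.25
and peak rate > 1 Hz (both strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session import BehaviorTrack


class UndefinedCurveError(ValueError):
    """Tuning curve undefined (no occupancy, or all-zero rates)."""


@dataclass
class TuningCurve:
    rates_hz: np.ndarray          # NaN where occupancy is zero (masked)
    occupancy_s: np.ndarray
    bin_centers_cm: np.ndarray
    peak_rate_hz: float
    selectivity: float
    is_place_cell: bool


def tuning_curve(spike_times: np.ndarray, behavior: BehaviorTrack,
                 n_bins: int = 36, track_cm: float = 90.0,
                 speed_min_cm_s: float = 3.0,
                 sampling_rate_hz: float | None = None) -> TuningCurve:
    """Occupancy-normalized firing rate over spatial bins (speed-filtered).

    Bins are half-open [b*w, (b+1)*w) cm.  Zero-occupancy bins get NaN rate
    and are excluded from downstream statistics.
    """
    t = np.asarray(behavior.t, dtype=float)
    pos = np.asarray(behavior.position_cm, dtype=float)
    speed = np.asarray(behavior.speed_cm_s, dtype=float)
    if sampling_rate_hz is None:
        sampling_rate_hz = 1.0 / float(np.median(np.diff(t)))
    dt = 1.0 / sampling_rate_hz
    width = track_cm / n_bins
    moving = speed > speed_min_cm_s
    bin_of = np.minimum((pos / width).astype(int), n_bins - 1)
    occupancy = np.bincount(bin_of[moving], minlength=n_bins) * dt
    spikes = np.asarray(spike_times, dtype=float)
    if spikes.size:
        si = np.clip(np.searchsorted(t, spikes, side="right") - 1, 0, t.size - 1)
        ok = moving[si]
        spike_counts = np.bincount(bin_of[si[ok]], minlength=n_bins).astype(float)
    else:
        spike_counts = np.zeros(n_bins)
    if np.all(occupancy == 0):
        raise UndefinedCurveError("no occupied bins above the speed threshold")
    rates = np.full(n_bins, np.nan)
    occ = occupancy > 0
    rates[occ] = spike_counts[occ] / occupancy[occ]
    peak = float(np.nanmax(rates))
    try:
        sel = spatial_selectivity(rates)
    except UndefinedCurveError:
        sel = np.nan
    centers = (np.arange(n_bins) + 0.5) * width
    return TuningCurve(rates_hz=rates, occupancy_s=occupancy,
                       bin_centers_cm=centers, peak_rate_hz=peak,
                       selectivity=sel,
                       is_place_cell=bool(np.isfinite(sel) and sel > 0.25 and peak > 1.0))


def spatial_selectivity(rates_hz: np.ndarray, n_bins: int | None = None) -> float:
    """One minus the circular variance of the tuning curve.

    Bin b maps to angle 2*pi*(b + 0.5)/n; selectivity is the rate-weighted
    resultant length |sum r_b e^{i theta_b}| / sum r_b over defined bins.
    """
    rates = np.asarray(rates_hz, dtype=float)
    n = n_bins if n_bins is not None else rates.size
    defined = np.isfinite(rates)
    r = rates[defined]
    if r.size == 0 or np.sum(r) <= 0:
        raise UndefinedCurveError("all-zero or undefined rates")
    theta = 2.0 * np.pi * (np.flatnonzero(defined) + 0.5) / n
    return float(np.abs(np.sum(r * np.exp(1j * theta))) / np.sum(r))


def classify_place_cell(curve: TuningCurve, min_selectivity: float = 0.25,
                        min_peak_hz: float = 1.0) -> bool:
    """Place cell iff selectivity > 0.25 AND peak rate > 1 Hz (strict)."""
    return bool(np.isfinite(curve.selectivity)
                and curve.selectivity > min_selectivity
                and curve.peak_rate_hz > min_peak_hz)


def tuning_similarity(curve_a: TuningCurve, curve_b: TuningCurve) -> float:
    """Spearman correlation of two tuning curves over jointly defined bins."""
    a, b = curve_a.rates_hz, curve_b.rates_hz
    joint = np.isfinite(a) & np.isfinite(b)
    if np.count_nonzero(joint) < 3:
        raise ValueError("fewer than 3 jointly defined bins")
    if np.ptp(a[joint]) == 0 or np.ptp(b[joint]) == 0:
        raise ValueError("constant curve; correlation undefined")
    rho, _ = stats.spearmanr(a[joint], b[joint])
    return float(rho)


def synchrony_vs_tuning(pairs, n_permutations: int = 10000,
                        seed: int | np.random.Generator = 0):
    """Spearman rho between pairwise synchronization strength and tuning
    similarity, with a permutation p-value.

    ``pairs`` is a sequence of (sync_strength, similarity).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.asarray([(s, c) for s, c in pairs
                      if np.isfinite(s) and np.isfinite(c)], dtype=float)
    if arr.shape[0] < 5:
        raise ValueError("need at least 5 pairs with defined values")
    strength, sim = arr[:, 0], arr[:, 1]
    if np.ptp(strength) == 0 or np.ptp(sim) == 0:
        raise ValueError("degenerate input; correlation undefined")
    rho, _ = stats.spearmanr(strength, sim)
    count = 0
    for _ in range(n_permutations):
        r, _ = stats.spearmanr(strength, rng.permutation(sim))
        if abs(r) >= abs(rho):
            count += 1
    return float(rho), count / n_permutations


def tuning_table(curves: dict) -> pd.DataFrame:
    """Long-format tuning export (cell_id, bin_index, bin_center_cm, rate_hz,
    occupancy_s)."""
    rows = []
    for cid, c in curves.items():
        for b in range(c.rates_hz.size):
            rows.append({"cell_id": cid, "bin_index": b,
                         "bin_center_cm": c.bin_centers_cm[b],
                         "rate_hz": c.rates_hz[b], "occupancy_s": c.occupancy_s[b]})
    return pd.DataFrame(rows)


def place_cell_summary(curves: dict) -> pd.DataFrame:
    return pd.DataFrame([
        {"cell_id": cid, "peak_rate_hz": c.peak_rate_hz,
         "selectivity": c.selectivity, "is_place_cell": c.is_place_cell}
        for cid, c in curves.items()
    ])
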