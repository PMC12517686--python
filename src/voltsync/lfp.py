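"""LFP ripple detection, ripple modulation of spiking, spectral analysis,
and theta phase-locking of synchronous events.

Ripples (120-240 Hz) are detected on the low-passed Hilbert envelope of the
band-passed LFP with a double threshold (mean + 3.5 SD to delimit, mean +
7 SD somewhere inside, >= 30 ms duration).  Phase-locking uses the
amplitude-weighted resultant vector V_k = A(t_k) e^{i phi(t_k)} of the
Hilbert phase/amplitude at event times; strength |sum V| / sum |V| lies in
[0, 1].  Phase convention: 0 rad at the peak of the band-passed oscillation,
±pi at the trough.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt, hilbert

from ._utils import merge_boolean_runs, wrap_phase

THETA_BAND_HZ = (4.0, 12.0)
RIPPLE_BAND_HZ = (120.0, 240.0)


class DegenerateSignalError(ValueError):
    """Signal has zero variance; thresholds are undefined."""


class UndefinedIndexError(ValueError):
    """Modulation index/strength undefined (no spikes or zero amplitudes)."""


@dataclass
class RippleEvent:
    start_s: float
    end_s: float
    peak_s: float
    peak_power: float

    @property
    def duration_ms(self) -> float:
        return (self.end_s - self.start_s) * 1000.0


@dataclass
class PhaseSeries:
    phi: np.ndarray            # radians in (-pi, pi], 0 at oscillation peak
    amp: np.ndarray            # instantaneous envelope
    band_hz: tuple
    sampling_rate_hz: float

    def at_times(self, t: np.ndarray):
        idx = np.clip(np.round(np.asarray(t, dtype=float) * self.sampling_rate_hz
                               ).astype(int), 0, self.phi.size - 1)
        return self.phi[idx], self.amp[idx]


@dataclass
class ThetaModulation:
    strength: float
    preferred_phase: float     # radians
    p_value: float
    n_events: int


def bandpass(signal: np.ndarray, sampling_rate_hz: float, band_hz, order: int = 4):
    """Zero-phase Butterworth band-pass."""
    lo, hi = band_hz
    nyq = sampling_rate_hz / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band_hz} outside (0, {nyq})")
    sos = butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float))


def lowpass(signal: np.ndarray, sampling_rate_hz: float, cutoff_hz: float,
            order: int = 2):
    sos = butter(order, cutoff_hz / (sampling_rate_hz / 2.0), btype="low", output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float))


def detect_ripples(samples: np.ndarray, sampling_rate_hz: float,
                   band_hz=RIPPLE_BAND_HZ, envelope_lowpass_hz: float = 20.0,
                   upper_sd: float = 7.0, lower_sd: float = 3.5,
                   min_duration_ms: float = 30.0) -> list[RippleEvent]:
    """Detect ripple events on the smoothed envelope of the band-passed LFP.

    Events are maximal runs above (mean + 3.5 SD) that contain at least one
    sample above (mean + 7 SD) and last >= 30 ms; boundaries sit at the
    lower-threshold crossings and the peak at the envelope maximum.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < sampling_rate_hz:
        raise ValueError("LFP shorter than 1 s")
    if np.ptp(samples) == 0:
        raise DegenerateSignalError("constant LFP")
    filtered = bandpass(samples, sampling_rate_hz, band_hz, order=4)
    env = lowpass(np.abs(hilbert(filtered)), sampling_rate_hz, envelope_lowpass_hz)
    mu, sd = float(np.mean(env)), float(np.std(env))
    if sd == 0:
        raise DegenerateSignalError("flat ripple-band envelope")
    lower, upper = mu + lower_sd * sd, mu + upper_sd * sd
    events = []
    for s, e in merge_boolean_runs(env > lower):
        if (e - s) / sampling_rate_hz < min_duration_ms / 1000.0:
            continue
        seg = env[s:e]
        if seg.max() <= upper:
            continue
        peak_i = s + int(np.argmax(seg))
        events.append(RippleEvent(start_s=s / sampling_rate_hz,
                                  end_s=e / sampling_rate_hz,
                                  peak_s=peak_i / sampling_rate_hz,
                                  peak_power=float(env[peak_i])))
    return events


def _count_in_intervals(spike_times: np.ndarray, intervals) -> int:
    if len(intervals) == 0 or spike_times.size == 0:
        return 0
    edges = np.asarray([[s, e] for s, e in intervals], dtype=float).ravel()
    pos = np.searchsorted(edges, spike_times, side="right")
    return int(np.count_nonzero(pos % 2 == 1))


def ripple_modulation_index(spike_times: np.ndarray, ripples, duration_s: float,
                            n_shuffles: int = 1000,
                            seed: int | np.random.Generator = 0):
    """(r_in - r_out) / (r_in + r_out) for firing inside vs outside ripples.

    Significance from circularly shifting the whole spike train by U(0, T)
    ``n_shuffles`` times; p is the two-sided tail fraction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    intervals = [(r.start_s, r.end_s) if isinstance(r, RippleEvent) else tuple(r)
                 for r in ripples]
    t_in = sum(e - s for s, e in intervals)
    if t_in <= 0:
        raise ValueError("total in-ripple duration must be positive")
    t_out = duration_s - t_in

    def index_of(train):
        n_in = _count_in_intervals(train, intervals)
        r_in = n_in / t_in
        r_out = (train.size - n_in) / t_out
        if r_in + r_out == 0:
            raise UndefinedIndexError("no spikes; index undefined")
        return (r_in - r_out) / (r_in + r_out)

    observed = index_of(spikes)
    if spikes.size == 0:
        raise UndefinedIndexError("no spikes; index undefined")
    shuffled = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shift = rng.uniform(0.0, duration_s)
        shuffled[k] = index_of(np.sort(np.mod(spikes + shift, duration_s)))
    hi = np.mean(shuffled >= observed)
    lo = np.mean(shuffled <= observed)
    p = min(1.0, 2.0 * min(hi, lo))
    return float(observed), float(p)


def co_occurrence(event_times: np.ndarray, intervals):
    """Co-occurrence percentages between point events and intervals.

    Returns (pct_intervals_containing_event, pct_events_inside_any_interval,
    empty_input_flag).
    """
    events = np.sort(np.asarray(event_times, dtype=float))
    empty = events.size == 0 or len(intervals) == 0
    if empty:
        return 0.0, 0.0, True
    hit_intervals = sum(
        1 for s, e in intervals
        if np.searchsorted(events, e, "left") > np.searchsorted(events, s, "left"))
    n_inside = _count_in_intervals(events, list(intervals))
    return (100.0 * hit_intervals / len(intervals),
            100.0 * n_inside / events.size, False)


def triggered_average(signal: np.ndarray, sampling_rate_hz: float,
                      trigger_times: np.ndarray, halfwidth_s: float):
    """Trigger-aligned mean of a signal (±halfwidth window).

    Triggers too close to an edge are dropped.  Returns
    (mean_trace, per_trigger_matrix, n_dropped).
    """
    signal = np.asarray(signal, dtype=float)
    half = int(round(halfwidth_s * sampling_rate_hz))
    centers = np.round(np.asarray(trigger_times, dtype=float) * sampling_rate_hz
                       ).astype(int)
    ok = (centers >= half) & (centers < signal.size - half)
    n_dropped = int(np.count_nonzero(~ok))
    centers = centers[ok]
    if centers.size == 0:
        raise ValueError("no trigger fully inside the recording")
    mat = signal[centers[:, None] + np.arange(-half, half + 1)]
    return mat.mean(axis=0), mat, n_dropped


def psd_fft(trace: np.ndarray, sampling_rate_hz: float, nfft: int = 16384):
    """One-sided FFT power spectrum of a (zero-padded) trace.

    Power is the squared magnitude of the Fourier coefficients on the grid
    fs * k / nfft.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size > nfft:
        raise ValueError("trace longer than nfft")
    coeffs = np.fft.rfft(trace, n=nfft)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sampling_rate_hz)
    return freqs, np.abs(coeffs) ** 2


def ripple_band_power(power: np.ndarray, freqs: np.ndarray,
                      band_hz=RIPPLE_BAND_HZ) -> float:
    """Sum of spectral power inside the ripple band."""
    lo, hi = band_hz
    if freqs.min() > lo or freqs.max() < hi:
        raise ValueError("frequency grid does not cover the band")
    sel = (freqs >= lo) & (freqs <= hi)
    return float(np.sum(power[sel]))


def phase_series(signal: np.ndarray, sampling_rate_hz: float,
                 band_hz=THETA_BAND_HZ, order: int = 4) -> PhaseSeries:
    """Instantaneous phase and amplitude of a band via the Hilbert transform."""
    filtered = bandpass(signal, sampling_rate_hz, band_hz, order=order)
    analytic = hilbert(filtered)
    return PhaseSeries(phi=wrap_phase(np.angle(analytic)), amp=np.abs(analytic),
                       band_hz=tuple(band_hz), sampling_rate_hz=sampling_rate_hz)


def vector_modulation(phases: np.ndarray, amplitudes: np.ndarray):
    """Amplitude-weighted resultant: (strength in [0,1], preferred phase)."""
    amps = np.asarray(amplitudes, dtype=float)
    total = np.sum(amps)
    if total <= 0:
        raise UndefinedIndexError("all amplitudes zero; modulation undefined")
    v = np.sum(amps * np.exp(1j * np.asarray(phases, dtype=float)))
    return float(np.abs(v) / total), float(np.angle(v))


def event_phase_modulation(event_times: np.ndarray, ps: PhaseSeries,
                           duration_s: float, n_shuffles: int = 1000,
                           seed: int | np.random.Generator = 0) -> ThetaModulation:
    """Phase-locking of events to an oscillation, with a uniform-shuffle null.

    p = fraction of ``n_shuffles`` uniform event-time redraws whose strength
    reaches the observed strength.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = np.asarray(event_times, dtype=float)
    if events.size == 0:
        raise ValueError("need at least one event")
    phi, amp = ps.at_times(events)
    strength, preferred = vector_modulation(phi, amp)
    count = 0
    for _ in range(n_shuffles):
        t = rng.uniform(0.0, duration_s, size=events.size)
        sphi, samp = ps.at_times(t)
        s, _ = vector_modulation(sphi, samp)
        if s >= strength:
            count += 1
    return ThetaModulation(strength=strength, preferred_phase=preferred,
                           p_value=count / n_shuffles, n_events=events.size)


def phase_deviation_histogram(event_times: np.ndarray, ps: PhaseSeries,
                              preferred_phase: float, bin_deg: float = 10.0):
    """Signed circular deviations of event phases from the preferred phase.

    Returns (bin_centers_deg, counts, deviations_deg) with deviations wrapped
    to (-180, 180].
    """
    phi, _ = ps.at_times(np.asarray(event_times, dtype=float))
    dev_deg = np.degrees(wrap_phase(phi - preferred_phase))
    edges = np.arange(-180.0, 180.0 + bin_deg, bin_deg)
    counts, _ = np.histogram(dev_deg, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, counts, dev_deg
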