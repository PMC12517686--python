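"""Synthetic voltage-imaging sessions with a complete ground-truth ledger.

The generator emulates the statistical structure the analysis assumes, not
the biophysics: state-dependent theta (slower in immobility), ripples
restricted to immobility, lognormal baseline firing with theta phase-locked
spiking, brief (~25 ms) synchronous ensembles recruiting a configurable
fraction of cells at theta phases drawn from a von Mises distribution,
coherent intracellular theta whose pairwise coherence decays with soma
distance, Gaussian place fields on a 90 cm one-way track, and a
negative-going fluorescence sensor with bleaching and shot-like noise.
Every random draw flows from the single mandatory seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import i0 as bessel_i0

from .session import SessionBundle, CellTrace, LfpTrace, BehaviorTrack
from .synchrony import theta_cycle_boundaries
from .lfp import bandpass, lowpass
from ._utils import wrap_phase, in_any_interval


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic session (defaults follow the
    recording protocol the analysis targets)."""
    seed: int
    n_cells: int = 14
    duration_s: float = 180.0
    imaging_rate_hz: float = 2000.0
    lfp_rate_hz: float = 8000.0
    track_cm: float = 90.0
    # behavior
    loco_speed_cm_s: float = 8.3
    loco_bout_mean_s: float = 6.5
    immo_bout_mean_s: float = 5.5
    transition_s: float = 1.0
    # LFP
    theta_hz_loco: float = 8.0
    theta_hz_immo: float = 7.0
    theta_amp_uv: float = 150.0
    lfp_noise_uv: float = 60.0
    ripple_rate_immo_hz: float = 0.04
    ripple_amp_sd: float = 8.0         # burst amplitude in units of band-passed noise SD
    ripple_freq_hz: tuple = (150.0, 200.0)
    ripple_duration_ms: tuple = (60.0, 100.0)
    # spiking
    base_rate_median_hz: float = 3.0
    base_rate_sigma_log: float = 0.35
    immobility_rate_gain: float = 1.4
    theta_lock_kappa: float = 0.8
    theta_lock_phase: float = 0.0      # rad, 0 = theta peak
    refractory_ms: float = 2.0
    ripple_suppression: bool = True
    # synchronous ensembles
    sync_rate_hz: float = 1.0
    sync_window_ms: float = 25.0
    participation_p: float = 0.4
    sync_theta_kappa: float = 4.0
    sync_theta_phase: float = -np.pi / 6.0   # late rising phase near the peak
    anti_correlated_fields: bool = False
    # place fields
    place_cell_fraction: float = 0.4
    field_sigma_cm: float = 5.0
    field_floor: float = 0.2
    # fluorescence rendering
    f_base: float = 1000.0
    bleach_tau_s: float = 800.0
    noise_sd: float = 0.005            # white noise as a fraction of F_base
    spike_amp: float = 0.05            # dF/F spike amplitude (>= 8x effective noise SD)
    spike_fwhm_ms: float = 1.2
    subvm_theta_amp: float = 0.012
    sync_bump_amp: float = 0.004
    shared_theta_weight: float = 0.75
    local_theta_weight: float = 0.55
    coherence_length_um: float = 400.0
    fov_um: tuple = (1400.0, 1200.0)
    min_soma_dist_um: float = 70.0

    def validate(self) -> None:
        if not (0.0 <= self.participation_p <= 1.0 and
                0.0 <= self.place_cell_fraction <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.participation_p * self.n_cells < 2:
            raise ValueError("participation_p * n_cells < 2: ensembles infeasible")
        if min(self.sync_rate_hz, self.ripple_rate_immo_hz) < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class GroundTruth:
    """Generator ledger sufficient to score every detector."""
    true_spikes: dict                 # cell_id -> seconds
    true_sync_times: np.ndarray
    true_sync_participants: list      # per-event set of cell ids
    true_fields: dict                 # cell_id -> center_cm or None
    true_theta_phase: np.ndarray      # radians per LFP sample
    true_theta_phase_imaging: np.ndarray
    true_ripples: list                # (start_s, end_s)
    state_schedule: list              # (label, start_s, end_s)
    centroids: dict = field(default_factory=dict)
    subvm_true: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "true_spikes": {k: list(map(float, v)) for k, v in self.true_spikes.items()},
            "true_sync_times": list(map(float, self.true_sync_times)),
            "true_sync_participants": [sorted(p) for p in self.true_sync_participants],
            "true_fields": {k: (None if v is None else float(v))
                            for k, v in self.true_fields.items()},
            "true_ripples": [[float(s), float(e)] for s, e in self.true_ripples],
            "state_schedule": [[lab, float(s), float(e)]
                               for lab, s, e in self.state_schedule],
            "centroids": {k: list(map(float, v)) for k, v in self.centroids.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)


def _smooth_noise(rng, n, sampling_rate_hz, cutoff_hz=0.5):
    return lowpass(rng.standard_normal(n), sampling_rate_hz, cutoff_hz)


def generate_behavior(config: GeneratorConfig, rng: np.random.Generator):
    """Alternating locomotion/immobility bouts with speed ramps in between.

    Locomotion speed fluctuates around a per-bout target near 8.3 cm/s
    (always above the 3 cm/s threshold); immobility speed stays below
    1 cm/s.  Position advances during locomotion and wraps at the track end
    (one-way loop).  Returns (BehaviorTrack, state_schedule).
    """
    fs = config.imaging_rate_hz
    n = int(round(config.duration_s * fs))
    speed = np.zeros(n)
    schedule = []
    t_cur = 0.0
    last_speed = 0.3
    state = "locomotion"
    while t_cur < config.duration_s:
        if state == "locomotion":
            bout = float(np.clip(rng.exponential(config.loco_bout_mean_s), 3.0, 20.0))
            target = float(np.clip(rng.normal(config.loco_speed_cm_s, 1.2), 4.5, 14.0))
        else:
            bout = float(np.clip(rng.exponential(config.immo_bout_mean_s), 2.0, 15.0))
            target = float(rng.uniform(0.1, 0.5))
        # transition ramp into the bout
        ramp_end = min(t_cur + config.transition_s, config.duration_s)
        i0_, i1_ = int(t_cur * fs), int(ramp_end * fs)
        if i1_ > i0_:
            speed[i0_:i1_] = np.linspace(last_speed, target, i1_ - i0_)
            schedule.append(("transition", i0_ / fs, i1_ / fs))
        t_cur = ramp_end
        bout_end = min(t_cur + bout, config.duration_s)
        j0, j1 = int(t_cur * fs), int(bout_end * fs)
        if j1 > j0:
            wobble = _smooth_noise(rng, j1 - j0, fs, cutoff_hz=0.8)
            wobble = wobble / max(np.std(wobble), 1e-12)
            if state == "locomotion":
                speed[j0:j1] = np.clip(target + 0.8 * wobble, 3.2, 16.0)
            else:
                speed[j0:j1] = np.clip(target + 0.15 * wobble, 0.0, 0.9)
            schedule.append((state, j0 / fs, j1 / fs))
        last_speed = speed[j1 - 1] if j1 > j0 else last_speed
        t_cur = bout_end
        state = "immobility" if state == "locomotion" else "locomotion"
    position = np.mod(np.cumsum(speed) / fs, config.track_cm)
    track = BehaviorTrack(t=np.arange(n) / fs, position_cm=position,
                          speed_cm_s=speed, track_length_cm=config.track_cm)
    return track, schedule


def _state_mask(schedule, label, n, fs):
    mask = np.zeros(n, dtype=bool)
    for lab, s, e in schedule:
        if lab == label:
            mask[int(s * fs):int(e * fs)] = True
    return mask


def generate_lfp(config: GeneratorConfig, schedule, rng: np.random.Generator):
    """State-dependent theta plus pink noise plus immobility-restricted ripples.

    Returns (LfpTrace, true_theta_phase (LFP rate), true_ripples).
    """
    fs = config.lfp_rate_hz
    n = int(round(config.duration_s * fs))
    freq = np.full(n, 0.5 * (config.theta_hz_loco + config.theta_hz_immo))
    freq[_state_mask(schedule, "locomotion", n, fs)] = config.theta_hz_loco
    freq[_state_mask(schedule, "immobility", n, fs)] = config.theta_hz_immo
    freq = lowpass(freq, fs, 0.5)
    phase = 2.0 * np.pi * np.cumsum(freq) / fs
    amp_mod = 1.0 + 0.2 * np.sin(2.0 * np.pi * 0.07 * np.arange(n) / fs
                                 + rng.uniform(0, 2 * np.pi))
    theta = config.theta_amp_uv * amp_mod * np.cos(phase)

    # pink (1/f) background
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f_grid = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(f_grid)
    scale[1:] = 1.0 / np.sqrt(f_grid[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n=n)
    pink *= config.lfp_noise_uv / np.std(pink)

    band_sd = float(np.std(bandpass(pink, fs, (120.0, 240.0))))
    samples = theta + pink
    ripples = []
    for lab, s, e in schedule:
        if lab != "immobility" or (e - s) < 0.6:
            continue
        n_rip = rng.poisson(config.ripple_rate_immo_hz * (e - s))
        for _ in range(n_rip):
            dur = rng.uniform(*config.ripple_duration_ms) / 1000.0
            t0 = rng.uniform(s + 0.15, e - 0.15 - dur)
            f_rip = rng.uniform(*config.ripple_freq_hz)
            i0_, i1_ = int(t0 * fs), int((t0 + dur) * fs)
            tt = np.arange(i1_ - i0_) / fs
            env = np.hanning(i1_ - i0_)
            samples[i0_:i1_] += (config.ripple_amp_sd * band_sd * env
                                 * np.cos(2 * np.pi * f_rip * tt))
            ripples.append((t0, t0 + dur))
    ripples.sort()
    return (LfpTrace(samples=samples, sampling_rate_hz=fs),
            wrap_phase(phase), ripples)


def _assign_fields(config: GeneratorConfig, rng: np.random.Generator):
    """Field centers per cell; None for untuned cells.

    With ``anti_correlated_fields`` every cell is tuned and split into two
    assemblies whose members hold maximally spaced fields, while the paired
    assembly holds nearby fields — co-participating (same-assembly) pairs
    then have dissimilar tuning.
    """
    cell_ids = [f"c{i:02d}" for i in range(config.n_cells)]
    fields = {cid: None for cid in cell_ids}
    if config.anti_correlated_fields:
        half = config.n_cells // 2
        spacing = config.track_cm / half
        for k in range(half):
            fields[cell_ids[k]] = (k + 0.25) * spacing
        for k in range(config.n_cells - half):
            fields[cell_ids[half + k]] = ((k + 0.25) * spacing + 0.35 * config.field_sigma_cm) \
                % config.track_cm
    else:
        n_pc = int(round(config.place_cell_fraction * config.n_cells))
        tuned = rng.choice(config.n_cells, size=n_pc, replace=False)
        centers = rng.uniform(0, config.track_cm, size=n_pc)
        for k, idx in enumerate(tuned):
            fields[cell_ids[idx]] = float(centers[k])
    return cell_ids, fields


def _field_gain(position_cm, center_cm, sigma_cm, track_cm, floor):
    """Circular Gaussian place-field gain with unit track-average."""
    d = np.abs(position_cm - center_cm)
    d = np.minimum(d, track_cm - d)
    g = np.exp(-0.5 * (d / sigma_cm) ** 2)
    mean_g = sigma_cm * np.sqrt(2 * np.pi) / track_cm  # circular-Gaussian track average
    peak = (1.0 - floor) / mean_g
    return floor + peak * g


def generate_spikes(config: GeneratorConfig, behavior: BehaviorTrack,
                    theta_phase_img: np.ndarray, true_ripples, schedule,
                    rng: np.random.Generator):
    """Inhomogeneous-Poisson background spikes plus injected ensembles.

    Returns (true_spikes dict, sync_times, sync_participants, fields dict).
    """
    fs = config.imaging_rate_hz
    n = theta_phase_img.size
    cell_ids, fields = _assign_fields(config, rng)
    loco = _state_mask(schedule, "locomotion", n, fs)
    immo = _state_mask(schedule, "immobility", n, fs)
    state_gain = np.ones(n)
    state_gain[immo] = config.immobility_rate_gain
    theta_gain = np.exp(config.theta_lock_kappa
                        * np.cos(theta_phase_img - config.theta_lock_phase)) \
        / bessel_i0(config.theta_lock_kappa)
    suppress = np.zeros(n, dtype=bool)
    if config.ripple_suppression:
        for s, e in true_ripples:
            suppress[int(s * fs):int(e * fs)] = True

    base_rates = {cid: config.base_rate_median_hz
                  * np.exp(rng.normal(0.0, config.base_rate_sigma_log))
                  for cid in cell_ids}
    background = {}
    for cid in cell_ids:
        gain = state_gain * theta_gain
        if fields[cid] is not None:
            fg = _field_gain(behavior.position_cm, fields[cid],
                             config.field_sigma_cm, config.track_cm,
                             config.field_floor)
            gain = gain * np.where(loco, fg, 1.0)
        lam = base_rates[cid] * gain
        lam[suppress] = 0.0
        hits = rng.random(n) < lam / fs
        background[cid] = np.flatnonzero(hits) / fs

    # synchronous ensembles at von Mises theta phases, outside ripples
    n_events = rng.poisson(config.sync_rate_hz * config.duration_s)
    bounds = theta_cycle_boundaries(theta_phase_img)
    sync_times = []
    attempts = 0
    while len(sync_times) < n_events and attempts < 20 * n_events:
        attempts += 1
        k = rng.integers(0, bounds.size - 1)
        psi = np.mod(rng.vonmises(config.sync_theta_phase,
                                  config.sync_theta_kappa), 2 * np.pi)
        t_ev = (bounds[k] + psi / (2 * np.pi) * (bounds[k + 1] - bounds[k])) / fs
        if t_ev < 0.2 or t_ev > config.duration_s - 0.2:
            continue
        if in_any_interval(np.array([t_ev]), true_ripples)[0]:
            continue
        sync_times.append(float(t_ev))
    sync_times = np.sort(np.asarray(sync_times))

    half_w = config.sync_window_ms / 2000.0
    participants = []
    sync_spikes = {cid: [] for cid in cell_ids}
    if config.anti_correlated_fields:
        half = config.n_cells // 2
        assemblies = [set(cell_ids[:half]), set(cell_ids[half:])]
        p_in = min(1.0, 2.0 * config.participation_p)
    for j, t_ev in enumerate(sync_times):
        if config.anti_correlated_fields:
            pool = assemblies[j % 2]
            members = {cid for cid in pool if rng.random() < p_in}
        else:
            members = {cid for cid in cell_ids
                       if rng.random() < config.participation_p}
        for cid in members:
            t_spk = t_ev + rng.uniform(-half_w, half_w)
            t_spk = np.round(t_spk * fs) / fs
            sync_spikes[cid].append(float(np.clip(t_spk, 0.0, config.duration_s - 1.0 / fs)))
        participants.append(members)

    refr = config.refractory_ms / 1000.0
    true_spikes = {}
    for cid in cell_ids:
        t_bg = background[cid]
        t_sync = np.asarray(sync_spikes[cid])
        times = np.concatenate((t_bg, t_sync))
        is_sync = np.concatenate((np.zeros(t_bg.size, bool), np.ones(t_sync.size, bool)))
        order = np.argsort(times, kind="stable")
        times, is_sync = times[order], is_sync[order]
        kept_t, kept = [], -np.inf
        for t, s in zip(times, is_sync):
            if s or t - kept > refr:
                if not (s and kept_t and abs(t - kept_t[-1]) < 0.25 / fs):
                    kept_t.append(t)
                kept = t
        true_spikes[cid] = np.asarray(kept_t)
    return true_spikes, sync_times, participants, fields


def _place_centroids(config: GeneratorConfig, rng: np.random.Generator):
    pts = []
    while len(pts) < config.n_cells:
        cand = rng.uniform((0, 0), config.fov_um)
        if all(np.linalg.norm(cand - p) >= config.min_soma_dist_um for p in pts):
            pts.append(cand)
    return {f"c{i:02d}": pts[i] for i in range(config.n_cells)}


def _spike_kernel(config: GeneratorConfig):
    """Biexponential spike waveform sampled at the imaging rate.

    Built on a fine grid, time-rescaled so its FWHM equals
    ``spike_fwhm_ms`` exactly, then sampled with the peak on a sample.
    Returns (kernel, peak_index).
    """
    fs = config.imaging_rate_hz
    dt = 1e-5
    t = np.arange(0.0, 0.01, dt)
    k = np.exp(-t / 8e-4) - np.exp(-t / 2e-4)
    k /= k.max()
    above = np.flatnonzero(k >= 0.5)
    fwhm_fine = (above[-1] - above[0]) * dt
    scale = (config.spike_fwhm_ms / 1000.0) / fwhm_fine
    t_scaled = t * scale
    t_peak = t_scaled[int(np.argmax(k))]
    n_pre = int(np.ceil(t_peak * fs))
    n_post = int(np.ceil((t_scaled[-1] - t_peak) * fs))
    sample_t = t_peak + np.arange(-n_pre, n_post + 1) / fs
    kern = np.interp(sample_t, t_scaled, k, left=0.0, right=0.0)
    return kern, n_pre


def render_fluorescence(config: GeneratorConfig, true_spikes: dict,
                        theta_phase_img: np.ndarray, sync_times: np.ndarray,
                        rng: np.random.Generator, centroids: dict | None = None):
    """Raw negative-going fluorescence per cell with bleaching and noise.

    The intracellular theta of each cell mixes a shared theta source with
    spatially correlated local theta-band noise (correlation decaying with
    centroid distance), producing distance-dependent pairwise coherence.
    Returns (raw_f dict, subvm_true dict, centroids dict).
    """
    fs = config.imaging_rate_hz
    n = theta_phase_img.size
    cell_ids = list(true_spikes.keys())
    if centroids is None:
        centroids = _place_centroids(config, rng)
    amp_mod = 1.0 + 0.2 * np.sin(2 * np.pi * 0.06 * np.arange(n) / fs
                                 + rng.uniform(0, 2 * np.pi))
    shared = np.cos(theta_phase_img) * amp_mod
    shared = shared / np.std(shared)

    pos = np.asarray([centroids[cid] for cid in cell_ids])
    dmat = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    corr = np.exp(-dmat / config.coherence_length_um)
    chol = np.linalg.cholesky(corr + 1e-9 * np.eye(len(cell_ids)))
    local = np.empty((len(cell_ids), n))
    for i in range(len(cell_ids)):
        z = bandpass(rng.standard_normal(n), fs, (4.0, 12.0), order=2)
        local[i] = z / np.std(z)
    local = chol @ local

    bump = np.zeros(n)
    if np.size(sync_times):
        sig = int(0.03 * fs)
        kern = np.exp(-0.5 * (np.arange(-3 * sig, 3 * sig + 1) / sig) ** 2)
        for t_ev in np.atleast_1d(sync_times):
            c = int(round(t_ev * fs))
            a, b = max(0, c - 3 * sig), min(n, c + 3 * sig + 1)
            bump[a:b] += config.sync_bump_amp * kern[(a - c + 3 * sig):(b - c + 3 * sig)]

    kernel, k_peak = _spike_kernel(config)
    t_axis = np.arange(n) / fs
    bleach = np.exp(-t_axis / config.bleach_tau_s)
    raw_f, subvm_true = {}, {}
    a_w, b_w = config.shared_theta_weight, config.local_theta_weight
    for i, cid in enumerate(cell_ids):
        slow_noise = _smooth_noise(rng, n, fs, cutoff_hz=3.0)
        slow_noise *= 0.002 / max(np.std(slow_noise), 1e-12)
        sub = config.subvm_theta_amp * (a_w * shared + b_w * local[i]) + bump + slow_noise
        dff_true = sub.copy()
        idx = np.round(np.asarray(true_spikes[cid]) * fs).astype(int)
        for j in idx:
            j0, j1 = max(0, j - k_peak), min(n, j - k_peak + kernel.size)
            dff_true[j0:j1] += config.spike_amp * kernel[(j0 - j + k_peak):(j1 - j + k_peak)]
        noise = rng.normal(0.0, config.noise_sd * config.f_base, n)
        raw_f[cid] = config.f_base * bleach * (1.0 - dff_true) + noise
        subvm_true[cid] = sub
    return raw_f, subvm_true, centroids


def generate_session(config: GeneratorConfig):
    """Compose a full synthetic session; deterministic under config.seed.

    Returns (SessionBundle, GroundTruth).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_beh, rng_lfp, rng_spk, rng_flu = (np.random.default_rng(s)
                                          for s in ss.spawn(4))
    behavior, schedule = generate_behavior(config, rng_beh)
    lfp, theta_phase_lfp, ripples = generate_lfp(config, schedule, rng_lfp)
    ratio = int(round(config.lfp_rate_hz / config.imaging_rate_hz))
    theta_phase_img = theta_phase_lfp[::ratio]
    true_spikes, sync_times, participants, fields = generate_spikes(
        config, behavior, theta_phase_img, ripples, schedule, rng_spk)
    raw_f, subvm_true, centroids = render_fluorescence(
        config, true_spikes, theta_phase_img, sync_times, rng_flu)
    cells = [CellTrace(cell_id=cid, raw_f=raw_f[cid],
                       centroid_xy=np.asarray(centroids[cid]),
                       sampling_rate_hz=config.imaging_rate_hz)
             for cid in sorted(raw_f.keys())]
    bundle = SessionBundle(cells=cells, lfp=lfp, behavior=behavior,
                           session_id=f"synthetic-{config.seed}",
                           duration_s=config.duration_s)
    bundle.validate()
    truth = GroundTruth(
        true_spikes=true_spikes, true_sync_times=sync_times,
        true_sync_participants=participants, true_fields=fields,
        true_theta_phase=theta_phase_lfp,
        true_theta_phase_imaging=theta_phase_img,
        true_ripples=ripples, state_schedule=schedule,
        centroids=centroids, subvm_true=subvm_true,
    )
    return bundle, truth


def config_from_yaml(path) -> GeneratorConfig:
    import yaml
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return GeneratorConfig(**data)


def config_to_dict(config: GeneratorConfig) -> dict:
    return asdict(config)
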