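import numpy as np
import pytest
from scipy import stats

from voltsync import lfp as lf

FS = 8000.0


def _pink_noise(rng, n, fs, sd):
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    return x * sd / x.std()


def test_detect_ripples_finds_injected_burst():
    rng = np.random.default_rng(0)
    n = int(60 * FS)
    x = _pink_noise(rng, n, FS, 50.0)
    band_sd = np.std(lf.bandpass(x, FS, (120, 240)))
    t = np.arange(int(0.06 * FS)) / FS
    burst = 8.0 * band_sd * np.hanning(t.size) * np.cos(2 * np.pi * 160 * t)
    c0 = int(30.0 * FS)
    x[c0:c0 + t.size] += burst
    events = lf.detect_ripples(x, FS)
    assert len(events) == 1
    assert abs(events[0].peak_s - (30.0 + 0.03)) < 0.005


def test_detect_ripples_ignores_theta_and_short_bursts():
    t = np.arange(int(10 * FS)) / FS
    theta = 200.0 * np.cos(2 * np.pi * 8.0 * t) + 1e-6 * np.sin(2 * np.pi * 300 * t)
    assert lf.detect_ripples(theta, FS) == []

    rng = np.random.default_rng(1)
    x = _pink_noise(rng, int(60 * FS), FS, 50.0)
    band_sd = np.std(lf.bandpass(x, FS, (120, 240)))
    tt = np.arange(int(0.02 * FS)) / FS  # 20 ms: below the duration rule
    x[int(30 * FS):int(30 * FS) + tt.size] += (
        8.0 * band_sd * np.hanning(tt.size) * np.cos(2 * np.pi * 160 * tt))
    assert lf.detect_ripples(x, FS) == []


def test_detect_ripples_degenerate_input():
    with pytest.raises(lf.DegenerateSignalError):
        lf.detect_ripples(np.zeros(int(2 * FS)), FS)


def test_ripple_modulation_index_values():
    ripples = [(10.0, 10.05), (20.0, 20.05), (30.0, 30.05)]
    spikes = np.linspace(0.5, 9.5, 60)   # none inside ripples
    idx, _ = lf.ripple_modulation_index(spikes, ripples, 180.0, 50, seed=0)
    assert idx == -1.0
    # r_in = 6 Hz, r_out = 2 Hz -> (6-2)/(6+2) = 0.5 (1 s ripples for clean
    # arithmetic: 18 in-ripple spikes over 3 s, 354 outside over 177 s)
    ripples = [(10.0, 11.0), (20.0, 21.0), (30.0, 31.0)]
    in_spikes = np.concatenate([np.linspace(s + 0.01, e - 0.01, 6)
                                for s, e in ripples])
    out_spikes = np.concatenate([np.linspace(0.1, 9.9, 20),
                                 np.linspace(31.5, 179.5, 334)])
    spikes = np.sort(np.concatenate([in_spikes, out_spikes]))
    idx, _ = lf.ripple_modulation_index(spikes, ripples, 180.0, 50, seed=0)
    r_in, r_out = 6.0, 354 / 177.0
    assert idx == pytest.approx((r_in - r_out) / (r_in + r_out), abs=1e-9)


def test_ripple_modulation_index_antisymmetric_and_bounded():
    rng = np.random.default_rng(2)
    ripples = [(i * 10.0, i * 10.0 + 1.0) for i in range(1, 10)]
    spikes = np.sort(rng.uniform(0, 100, 300))
    idx, _ = lf.ripple_modulation_index(spikes, ripples, 100.0, 20, seed=0)
    assert -1.0 <= idx <= 1.0
    # swapping in/out periods flips the sign
    complement = [(0.0, 10.0)] + [(i * 10.0 + 1.0, (i + 1) * 10.0)
                                  for i in range(1, 9)] + [(91.0, 100.0)]
    idx2, _ = lf.ripple_modulation_index(spikes, complement, 100.0, 20, seed=0)
    assert idx2 == pytest.approx(-idx, abs=1e-9)


def test_co_occurrence_counting():
    assert lf.co_occurrence(np.array([1.0]), [(5.0, 6.0)])[:2] == (0.0, 0.0)
    pct_i, pct_e, flag = lf.co_occurrence(np.array([5.5, 7.5]),
                                          [(5.0, 6.0), (7.0, 8.0)])
    assert (pct_i, pct_e, flag) == (100.0, 100.0, False)
    pct_i, _, _ = lf.co_occurrence(np.array([1.2, 2.2, 3.2]),
                                   [(float(i), i + 0.99) for i in range(12)])
    assert pct_i == pytest.approx(25.0)
    assert lf.co_occurrence(np.empty(0), [(0.0, 1.0)])[2] is True


def test_triggered_average_alignment_and_edge_rule():
    t = np.arange(int(20 * FS)) / FS
    sig = np.cos(2 * np.pi * 2.0 * t)
    peaks = np.arange(2.0, 18.0, 0.5)  # all at signal peaks
    mean, mat, dropped = lf.triggered_average(sig, FS, peaks, 0.2)
    assert dropped == 0
    assert mean[mean.size // 2] == pytest.approx(1.0, abs=1e-6)
    _, _, dropped = lf.triggered_average(sig, FS, np.array([0.1, 10.0]), 1.0)
    assert dropped == 1
    single, mat, _ = lf.triggered_average(sig, FS, np.array([10.0]), 0.1)
    np.testing.assert_array_equal(single, mat[0])
    with pytest.raises(ValueError):
        lf.triggered_average(sig, FS, np.array([0.05]), 1.0)


def test_psd_fft_peak_and_parseval():
    fs = 2000.0
    t = np.arange(4000) / fs
    x = np.sin(2 * np.pi * 8.0 * t)
    freqs, power = lf.psd_fft(x, fs)
    assert abs(freqs[np.argmax(power)] - 8.0) < fs / 16384
    # Parseval on the full (two-sided) spectrum
    total = 2 * power[1:-1].sum() + power[0] + power[-1]
    assert total == pytest.approx(16384 * np.sum(x ** 2), rel=1e-9)
    _, zero = lf.psd_fft(np.zeros(100), fs)
    assert not zero.any()


def test_ripple_band_power_selects_band():
    fs = 2000.0
    t = np.arange(4000) / fs
    f, p160 = lf.psd_fft(np.sin(2 * np.pi * 160 * t), fs)
    f, p8 = lf.psd_fft(np.sin(2 * np.pi * 8 * t), fs)
    assert lf.ripple_band_power(p160, f) > 0.95 * p160.sum()
    assert lf.ripple_band_power(p8, f) < 0.01 * p8.sum()
    rng = np.random.default_rng(3)
    f, pw = lf.psd_fft(rng.standard_normal(4000), fs)
    frac = lf.ripple_band_power(pw, f) / pw.sum()
    assert frac == pytest.approx(120.0 / 1000.0, rel=0.25)


def test_phase_series_conventions():
    fs = 2000.0
    t = np.arange(int(20 * fs)) / fs
    x = np.cos(2 * np.pi * 8.0 * t)
    ps = lf.phase_series(x, fs, (4.0, 12.0))
    inner = slice(2000, -2000)
    assert np.std(ps.amp[inner]) < 0.02
    # phase zero at signal peaks
    peak_idx = (np.arange(2, 150) * fs / 8.0).astype(int)
    assert np.max(np.abs(ps.phi[peak_idx])) < 0.05
    with pytest.raises(ValueError):
        lf.phase_series(x, fs, (4.0, 2000.0))


def test_phase_series_tracks_am_envelope():
    fs = 2000.0
    t = np.arange(int(30 * fs)) / fs
    env = 1.0 + 0.5 * np.sin(2 * np.pi * 0.2 * t)
    x = env * np.cos(2 * np.pi * 8.0 * t)
    ps = lf.phase_series(x, fs, (4.0, 12.0))
    inner = slice(4000, -4000)
    r = np.corrcoef(ps.amp[inner], env[inner])[0, 1]
    assert r > 0.99


def test_event_phase_modulation_exact_cases():
    fs = 2000.0
    ps = lf.PhaseSeries(phi=np.array([np.pi / 4, np.pi / 4, np.pi / 4 - np.pi,
                                      np.pi / 4]),
                        amp=np.ones(4), band_hz=(4, 12), sampling_rate_hz=fs)
    s, phi = lf.vector_modulation(np.full(5, np.pi / 4), np.ones(5))
    assert s == pytest.approx(1.0) and phi == pytest.approx(np.pi / 4)
    s, _ = lf.vector_modulation(np.array([0.3, 0.3 - np.pi]), np.ones(2))
    assert s == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(lf.UndefinedIndexError):
        lf.vector_modulation(np.array([0.1]), np.zeros(1))


def test_event_phase_modulation_null_is_flat():
    fs = 2000.0
    t = np.arange(int(60 * fs)) / fs
    x = np.cos(2 * np.pi * 8.0 * t)
    ps = lf.phase_series(x, fs, (4, 12))
    rng = np.random.default_rng(4)
    events = rng.uniform(1, 59, 1000)
    mod = lf.event_phase_modulation(events, ps, 60.0, n_shuffles=200, seed=5)
    assert mod.strength < 0.1
    assert mod.p_value > 0.05


def test_modulation_strength_invariant_under_global_rotation():
    rng = np.random.default_rng(6)
    phases = rng.vonmises(0.5, 2.0, 300)
    amps = rng.uniform(0.5, 2.0, 300)
    s1, p1 = lf.vector_modulation(phases, amps)
    s2, p2 = lf.vector_modulation(phases + 1.0, amps)
    assert s2 == pytest.approx(s1)
    from voltsync._utils import wrap_phase
    assert wrap_phase(p2 - p1) == pytest.approx(1.0, abs=1e-9)


def test_phase_deviation_histogram_exact_bins():
    fs = 2000.0
    ps = lf.PhaseSeries(phi=np.full(int(fs), 0.5), amp=np.ones(int(fs)),
                        band_hz=(4, 12), sampling_rate_hz=fs)
    events = np.full(10, 0.25)
    centers, counts, dev = lf.phase_deviation_histogram(events, ps, 0.5)
    assert counts.sum() == 10
    assert np.all(np.abs(dev) < 1e-9)
    centers, counts, dev = lf.phase_deviation_histogram(events, ps, 0.5 - np.pi)
    assert np.all(np.isclose(np.abs(dev), 180.0))
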