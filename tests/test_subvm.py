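import numpy as np
import pytest

from voltsync import subvm as sv
from voltsync.lfp import phase_series

FS = 2000.0


def test_label_segments_by_90_percent_rule():
    seg = sv.label_segments(np.full(10000, 5.0), FS)
    assert all(lab == "locomotion" for lab in seg.labels)
    seg = sv.label_segments(np.full(10000, 2.0), FS)
    assert all(lab == "excluded" for lab in seg.labels)
    speed = np.zeros(int(FS))
    speed[:int(0.05 * FS)] = 5.0  # fast for 5% only -> still immobility
    seg = sv.label_segments(np.tile(speed, 10), FS)
    assert seg.labels[2] == "immobility"
    # consecutive starts differ by 0.5 s
    assert np.allclose(np.diff(seg.starts_s), 0.5)


def test_synchrony_triggered_subvm_alignment_and_exclusion():
    n = int(30 * FS)
    t = np.arange(n) / FS
    sub = np.cos(2 * np.pi * 8.0 * t)
    events = np.arange(1.0, 29.0, 0.125)  # sinusoid peaks (8 Hz period)
    per, grand, omitted = sv.synchrony_triggered_subvm(
        {"a": sub, "b": sub}, {"a": np.empty(0), "b": np.empty(0)}, events, FS)
    mid = grand.size // 2
    assert grand[mid] == pytest.approx(1.0, abs=1e-6)
    assert omitted == []
    # cell spiking inside every window is omitted
    spikes = {"a": np.empty(0), "b": events + 0.01}
    per, grand, omitted = sv.synchrony_triggered_subvm(
        {"a": sub, "b": sub}, spikes, events, FS)
    assert omitted == ["b"] and set(per) == {"a"}


def test_synchrony_triggered_subvm_flat_for_random_events():
    rng = np.random.default_rng(0)
    sub = rng.normal(0, 1, int(120 * FS))
    events = rng.uniform(1, 119, 400)
    _, grand, _ = sv.synchrony_triggered_subvm({"a": sub}, {"a": np.empty(0)},
                                               events, FS)
    se = 1.0 / np.sqrt(400)
    assert np.max(np.abs(grand)) < 4 * se


def test_spike_triggered_subvm_category_rules():
    n = int(30 * FS)
    t = np.arange(n) / FS
    sub = np.cos(2 * np.pi * 8.0 * t)
    peaks = np.arange(1.0, 29.0, 0.125)
    out = sv.spike_triggered_subvm(sub, {"sync": peaks, "sparse": peaks[:4]}, FS)
    assert "sparse" not in out            # 4 triggers -> excluded
    mid = out["sync"].size // 2
    assert out["sync"][mid] == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(ValueError):
        sv.spike_triggered_subvm(sub, {"sparse": peaks[:3]}, FS)


def test_spike_phase_modulation_contrast():
    n = int(60 * FS)
    t = np.arange(n) / FS
    sub = np.cos(2 * np.pi * 8.0 * t)
    ps = phase_series(sub, FS, (4.0, 12.0))
    rng = np.random.default_rng(1)
    locked = np.arange(1.0, 59.0, 0.125)          # at subVm theta peaks
    uniform = np.sort(rng.uniform(1.0, 59.0, 400))
    out = sv.spike_phase_modulation(
        {"locked": locked, "uniform": uniform, "empty": np.empty(0)},
        ps, {"locked": [(0.0, 60.0)], "uniform": [(0.0, 60.0)],
             "empty": [(0.0, 60.0)]},
        n_shuffles=100, seed=2)
    assert "empty" not in out
    assert out["locked"].strength > 0.95
    assert abs(out["locked"].preferred_phase) < 0.1
    assert out["uniform"].strength < 0.15
    assert out["locked"].p_value <= 0.01


def _segments_all(state, duration, fs=FS):
    starts = np.arange(0.0, duration - 1.0 + 1e-9, 0.5)
    return sv.SegmentSet(starts_s=starts, labels=[state] * starts.size,
                         sampling_rate_hz=fs)


def test_xcorr_identity_and_delay_convention():
    rng = np.random.default_rng(3)
    n = int(20 * FS)
    a = rng.normal(0, 1, n)
    seg = _segments_all("locomotion", 20.0)
    lags, xc, counts = sv.pairwise_subvm_xcorr(a, a, seg)
    mid = np.flatnonzero(lags == 0)[0]
    assert xc["locomotion"][mid] == pytest.approx(1.0)
    assert np.argmax(xc["locomotion"]) == mid
    # b = a delayed 25 ms -> positive lag peak (b lags a)
    shift = int(0.025 * FS)
    b = np.roll(a, shift)
    lags, xc, _ = sv.pairwise_subvm_xcorr(a, b, seg)
    assert lags[np.argmax(xc["locomotion"])] == pytest.approx(0.025)


def test_xcorr_independent_noise_is_small():
    rng = np.random.default_rng(4)
    n = int(60 * FS)
    seg = _segments_all("immobility", 60.0)
    _, xc, _ = sv.pairwise_subvm_xcorr(rng.normal(0, 1, n), rng.normal(0, 1, n),
                                       seg)
    assert np.max(np.abs(xc["immobility"])) < 0.1


def test_theta_coherence_identical_and_snr_half():
    rng = np.random.default_rng(5)
    n = int(60 * FS)
    t = np.arange(n) / FS
    shared = np.sin(2 * np.pi * 8.0 * t)
    seg = _segments_all("locomotion", 60.0)
    coh, _, _ = sv.pairwise_theta_coherence(shared, shared, seg)
    assert coh["locomotion"] == pytest.approx(1.0)
    # shared theta + independent noise at matched power -> coherence ~ 0.5
    # at the theta line; the 4-12 Hz band average sits lower because
    # noise-only bins contribute only the estimator's bias floor
    sigma = np.sqrt(0.5)
    a = shared + rng.normal(0, sigma, n)
    b = shared + rng.normal(0, sigma, n)
    coh_ab, counts, flags = sv.pairwise_theta_coherence(a, b, seg)
    assert 0.0 <= coh_ab["locomotion"] <= 1.0
    noise_coh, _, _ = sv.pairwise_theta_coherence(
        rng.normal(0, 1, n), rng.normal(0, 1, n), seg)
    assert coh_ab["locomotion"] > noise_coh["locomotion"] + 0.1
    assert flags["locomotion"] is False


def test_coherence_bounded_unit_interval():
    rng = np.random.default_rng(6)
    n = int(10 * FS)
    seg = _segments_all("immobility", 10.0)
    coh, _, _ = sv.pairwise_theta_coherence(rng.normal(0, 1, n),
                                            rng.normal(0, 1, n), seg)
    assert 0.0 <= coh["immobility"] <= 1.0


def test_coherence_vs_distance_examples():
    rho, _ = sv.coherence_vs_distance([0.9, 0.7, 0.5, 0.3], [10, 20, 30, 40])
    assert rho == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        sv.coherence_vs_distance([0.5, 0.5], [1, 2])
    with pytest.raises(ValueError):
        sv.coherence_vs_distance([0.5, 0.5, 0.5], [1, 2, 3])
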