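import numpy as np
import pytest
from hypothesis import given, strategies as st

from voltsync import preprocess as prep

FS = 2000.0


def test_dff_constant_trace_is_zero():
    dff = prep.compute_dff(np.full(5000, 100.0), FS)
    np.testing.assert_allclose(dff, 0.0, atol=1e-12)


def test_dff_single_sample_dip_close_to_ten_percent():
    raw = np.full(5000, 100.0)
    raw[2500] = 90.0
    dff = prep.compute_dff(raw, FS)
    # oracle: windowed mean at that sample
    f0 = raw[2500 - 1000:2500 + 1001].mean()
    assert dff[2500] == pytest.approx((f0 - 90.0) / f0)
    assert dff[2500] == pytest.approx(0.1, rel=0.01)


def test_dff_removes_slow_bleach():
    t = np.arange(60000) / FS
    raw = 1000.0 * np.exp(-t / 100.0)
    dff = prep.compute_dff(raw, FS)
    assert np.max(np.abs(dff[2000:-2000])) < 0.005


@given(st.floats(0.1, 50.0))
def test_dff_invariant_to_multiplicative_rescaling(c):
    rng = np.random.default_rng(3)
    raw = 100.0 + rng.normal(0, 1, 6000)
    np.testing.assert_allclose(prep.compute_dff(raw, FS),
                               prep.compute_dff(c * raw, FS), atol=1e-9)


def test_highpass_residual_examples():
    ramp = np.linspace(0, 1, 4000)
    res = prep.highpass_residual(ramp, FS)
    assert np.max(np.abs(res[10:-10])) < 1e-12

    flat = np.zeros(4000)
    flat[2000] = 0.5
    res = prep.highpass_residual(flat, FS)
    assert res[2000] == pytest.approx(0.5)

    t = np.arange(8000) / FS
    sine = 0.1 * np.sin(2 * np.pi * 5.0 * t)
    res = prep.highpass_residual(sine, FS)
    assert np.max(np.abs(res)) < 0.01 * 0.1 * 10


def test_detect_spikes_recovers_injected_waveforms():
    rng = np.random.default_rng(7)
    n = 40000
    res = rng.normal(0, 0.005, n)
    kernel = np.array([0.2, 1.0, 0.6, 0.3, 0.1]) * 0.05  # 10x noise SD
    true_idx = np.arange(2000, 40000, 3700)[:10]
    for i in true_idx:
        res[i - 1:i + 4] += kernel
    times, amps, thr = prep.detect_spikes(res, FS)
    assert times.size == 10
    assert np.all(np.abs(times - true_idx / FS) <= 0.0005)
    assert np.all(amps > thr)


def test_detect_spikes_suppresses_pure_noise():
    rng = np.random.default_rng(11)
    res = rng.normal(0, 0.005, 100000)
    from scipy.signal import find_peaks
    n_maxima = find_peaks(res)[0].size
    times, _, _ = prep.detect_spikes(res, FS)
    assert times.size <= 0.01 * n_maxima


def test_small_amplitude_events_removed_by_top5_rule():
    rng = np.random.default_rng(2)
    res = rng.normal(0, 0.001, 40000)
    big_idx = np.arange(2000, 22000, 1000)   # 20 events, amp 1.0
    small_idx = np.arange(25000, 35000, 1000)  # 10 events, amp 0.2
    res[big_idx] += 1.0
    res[small_idx] += 0.2
    times, amps, _ = prep.detect_spikes(res, FS)
    # amplitude rule: keep only events >= 0.5 * mean(top 5%) = 0.5
    assert np.all(amps > 0.4)
    detected = np.round(times * FS).astype(int)
    assert not np.intersect1d(detected, small_idx).size


def test_snr_matches_definition_and_scales_linearly():
    rng = np.random.default_rng(5)
    res = rng.normal(0, 0.01, 40000)
    idx = np.arange(2000, 38000, 2000)
    res[idx] += 0.05
    t = idx / FS
    a = np.full(idx.size, 0.05)
    snr = prep.compute_snr(res, t, a, FS)
    assert snr == pytest.approx(5.0, rel=0.1)
    assert prep.compute_snr(res, t, 2 * a, FS) == pytest.approx(2 * snr)
    with pytest.raises(prep.UndefinedSnrError):
        prep.compute_snr(res, np.empty(0), np.empty(0), FS)


def _fake_activity(cid, snr, rate=2.0, fwhm=1.2):
    return prep.CellActivity(
        cell_id=cid, dff=np.zeros(10), hp_residual=np.zeros(10),
        spike_times=np.arange(int(rate * 10)) / max(rate, 1e-9),
        spike_amplitudes=np.ones(int(rate * 10)),
        detection_threshold=0.1, spike_threshold_v=0.1, snr=snr,
        subvm=np.zeros(10), mean_rate_hz=rate, waveform_fwhm_ms=fwhm,
        sampling_rate_hz=FS)


def test_qc_excludes_low_snr_cell():
    acts = [_fake_activity("a", 4.9), _fake_activity("b", 8.0)]
    cents = {"a": np.array([0.0, 0.0]), "b": np.array([500.0, 0.0])}
    included, _ = prep.qc_cells(acts, cents, 10.0)
    assert included == {"b"}
    assert acts[0].qc_flags["snr"] is False


def test_qc_pair_distance_drops_lower_snr_member():
    acts = [_fake_activity("a", 8.0), _fake_activity("b", 6.0)]
    cents = {"a": np.array([0.0, 0.0]), "b": np.array([50.0, 0.0])}
    included, _ = prep.qc_cells(acts, cents, 10.0)
    assert included == {"a"}


def test_session_with_eight_survivors_not_analyzable():
    acts = [_fake_activity(f"c{i}", 8.0) for i in range(8)]
    cents = {f"c{i}": np.array([200.0 * i, 0.0]) for i in range(8)}
    included, analyzable = prep.qc_cells(acts, cents, 10.0)
    assert len(included) == 8 and not analyzable


def test_extract_subvm_spikeless_returns_slow_trace():
    t = np.arange(8000) / FS
    dff = 0.01 * np.sin(2 * np.pi * 8 * t)
    res = prep.highpass_residual(dff, FS)
    subvm, thr = prep.extract_subvm(dff, res, np.empty(0), FS)
    np.testing.assert_array_equal(subvm, dff - res)
    assert np.isnan(thr)


def test_extract_subvm_interpolates_suprathreshold_hump():
    # a sharp spike defines the threshold; a separate broad suprathreshold
    # hump must be replaced by the straight line joining its flanks
    n = 8000
    dff = np.zeros(n)
    dff[1999:2004] = np.array([0.0, 0.6, 1.0, 0.6, 0.0])   # spike waveform
    hump = slice(5000, 5010)
    dff[hump] = 0.9                                        # 10-sample hump
    res = np.zeros(n)
    subvm, thr = prep.extract_subvm(dff, res, np.array([2001 / FS]), FS)
    assert 0.0 < thr < 0.9
    assert np.all(subvm <= thr + 1e-12)
    # flanking samples are 0, so the interpolated section is a line at ~0
    i0, i1 = 4999, 5010
    expected = np.interp(np.arange(i0, i1 + 1), [i0, i1], [dff[i0], dff[i1]])
    np.testing.assert_allclose(subvm[i0:i1 + 1], expected, atol=1e-12)


def test_extract_subvm_degenerate_all_above_threshold_warns():
    # spike waveform rises from a deep trough, putting the threshold below
    # the entire slow trace -> every sample is suprathreshold
    n = 8000
    dff = np.zeros(n)
    dff[3990:4001] = np.linspace(-0.5, 1.0, 11)
    dff[4000:4011] = np.linspace(1.0, 0.0, 11)
    res = dff.copy()  # slow trace = 0 everywhere
    with pytest.warns(RuntimeWarning):
        subvm, thr = prep.extract_subvm(dff, res, np.array([4000 / FS]), FS)
    assert thr < 0
    assert np.all(subvm == thr)


def test_subvm_never_exceeds_spike_threshold_on_synthetic_cells(processed_cells):
    acts, included, _ = processed_cells
    for a in acts:
        if np.isfinite(a.spike_threshold_v):
            assert np.all(a.subvm <= a.spike_threshold_v + 1e-12)
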