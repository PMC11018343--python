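"""Causal online detector: filter responses, RP identities, detection
logic, lockout/veto bookkeeping, causality and the closed loop."""

import numpy as np
import pytest
from scipy import signal as sps

from ripplecheck.core import ContinuousSignal, ValidationError
from ripplecheck.online import (
    closed_loop_session,
    design_online_filter,
    detect_online,
    online_band_filter,
    ripple_power,
)
from ripplecheck.synth import LfpSynthParams, constant_zones, generate_lfp


def _signal(data, fs=4000.0, roles=None):
    data = np.atleast_2d(data)
    roles = roles or ("hippocampal",) * data.shape[0]
    return ContinuousSignal(data, fs=fs, channel_roles=roles)


# ---------------------------------------------------------------------------
# filter and ripple power
# ---------------------------------------------------------------------------


def test_online_filter_frequency_response():
    """Frequency-response oracle: unity passband gain within 1 dB at
    180 Hz, and at least the stopband attenuation at 60 Hz."""
    sos = design_online_filter(4000.0)
    w, h = sps.sosfreqz(sos, worN=[60.0, 180.0], fs=4000.0)
    gain_db = 20 * np.log10(np.abs(h))
    assert abs(gain_db[1]) < 1.0
    assert gain_db[0] < -40.0


def test_online_filter_steady_state_sinusoid():
    fs = 4000.0
    t = np.arange(int(fs * 3)) / fs
    y, _ = online_band_filter(np.sin(2 * np.pi * 180 * t), fs)
    steady = y[int(fs) :]
    assert np.max(np.abs(steady)) == pytest.approx(1.0, abs=0.12)


def test_online_filter_zero_input_zero_output():
    y, _ = online_band_filter(np.zeros(1000), 4000.0)
    assert np.allclose(y, 0.0)


def test_online_filter_odd_order_rejected():
    with pytest.raises(ValidationError):
        design_online_filter(4000.0, order=7)


def test_ripple_power_constant_value():
    rp = ripple_power(np.full((1, 4000), 3.0), 4000.0)
    assert rp[-1] == pytest.approx(3.0)


def test_ripple_power_gain_linearity():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(2, 4000))
    np.testing.assert_allclose(ripple_power(2 * x, 4000.0), 2 * ripple_power(x, 4000.0))


def test_ripple_power_sinusoid_rms_identity():
    """RMS of a sinusoid of amplitude A is A/sqrt(2) for a window much
    longer than the period."""
    fs = 4000.0
    t = np.arange(int(fs)) / fs
    rp = ripple_power(5.0 * np.sin(2 * np.pi * 200 * t), fs, rms_window_s=0.1)
    assert rp[-1] == pytest.approx(5.0 / np.sqrt(2), rel=0.05)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def test_zero_signal_gives_empty_log():
    sig = _signal(np.zeros((2, 20000)), roles=("hippocampal", "cortical"))
    log = detect_online(sig, f=7.0)
    assert len(log) == 0


def _one_ripple_signal(seed=0, burst_dur=0.06, amp=160.0, on_cortical=False):
    params = LfpSynthParams(
        duration_s=10.0, ripple_rate_by_state={"reward_immobile": 0.0}, seed=seed
    )
    sig, _ = generate_lfp(params, constant_zones(10.0))
    t = sig.times() - 5.0
    sigma = burst_dur / (2 * np.sqrt(2 * np.log(10)))
    burst = amp * np.exp(-0.5 * (t / sigma) ** 2) * np.cos(2 * np.pi * 180 * t)
    for ch in sig.channels_with_role("hippocampal"):
        sig.data[ch] += burst
    if on_cortical:
        # artifacts reach the cortical electrode at least as strongly,
        # which is what the asymmetric [-40, +1.5] ms veto window targets
        sig.data[sig.channels_with_role("cortical")[0]] += 1.5 * burst
    t_start = 5.0 - burst_dur / 2
    return sig, t_start


def test_single_ripple_detected_with_plausible_latency():
    """One high-SNR ripple at f=7: exactly one (non-discarded) detection,
    10-60 ms after the ground-truth start."""
    sig, t_start = _one_ripple_signal()
    log = detect_online(sig, f=7.0, condition="disruption", seed=0)
    kept = log.detection_times(include_discarded=False)
    assert len(kept) == 1
    latency = kept[0] - t_start
    assert 0.010 <= latency <= 0.060


def test_simultaneous_cortical_burst_is_vetoed():
    sig, _ = _one_ripple_signal(on_cortical=True)
    log = detect_online(sig, f=7.0, condition="disruption", seed=0)
    kept = log.entries[~log.entries.discarded_by_lockout]
    assert len(kept) >= 1
    assert bool(kept.iloc[0]["vetoed"])
    assert len(log.stim_times()) == 0


def test_detection_count_nonincreasing_in_f(recording_cache):
    sig = recording_cache(1)["signal"]
    counts = [
        len(detect_online(sig, f=f, condition="no_stim", seed=1))
        for f in (5.0, 7.0, 9.0, 13.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_causality_by_truncation_equivalence(recording_cache):
    """Running the detector on a prefix reproduces the prefix of the log
    (up to the declared 1.5 ms veto deferral at the cut)."""
    sig = recording_cache(1)["signal"]
    full = detect_online(sig, f=7.0, condition="stim_control", seed=1)
    cut = sig.n_samples // 2
    prefix_sig = ContinuousSignal(
        sig.data[:, :cut], fs=sig.fs, t0=sig.t0, channel_roles=sig.channel_roles
    )
    prefix = detect_online(prefix_sig, f=7.0, condition="stim_control", seed=1)
    t_cut = sig.t0 + cut / sig.fs - 0.002
    a = full.entries[full.entries.t_detect_s < t_cut].reset_index(drop=True)
    b = prefix.entries[prefix.entries.t_detect_s < t_cut].reset_index(drop=True)
    assert a.equals(b)


def test_lockout_and_delay_invariants(recording_cache):
    sig = recording_cache(2)["signal"]
    for condition in ("disruption", "stim_control"):
        log = detect_online(sig, f=7.0, condition=condition, seed=2)
        stim = np.sort(log.stim_times())
        if len(stim) > 1:
            assert np.min(np.diff(stim)) >= 0.150 - 1e-9
        kept = log.entries[np.isfinite(log.entries.t_stim_s)]
        delays = kept.t_stim_s - kept.t_detect_s
        if condition == "stim_control":
            assert ((delays >= 0.150) & (delays <= 0.250)).all()
        else:
            assert np.allclose(delays, 0.001)


def test_missing_cortical_channel_disables_veto(caplog):
    sig = _signal(np.random.default_rng(1).normal(0, 20, size=(2, 20000)))
    with caplog.at_level("WARNING", logger="ripplecheck"):
        log = detect_online(sig, f=7.0)
    assert not log.entries.vetoed.any()
    assert any("veto disabled" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# closed loop
# ---------------------------------------------------------------------------


def test_closed_loop_no_stim_equals_open_loop():
    params = LfpSynthParams(duration_s=20.0, seed=5)
    open_sig, open_truth = generate_lfp(params, constant_zones(20.0))
    sig, log, truth = closed_loop_session(params, "no_stim", seed=5)
    np.testing.assert_array_equal(sig.data, open_sig.data)
    np.testing.assert_array_equal(truth.start_s, open_truth.start_s)
    assert len(log.stim_times()) == 0


def test_closed_loop_disruption_inserts_artifacts():
    params = LfpSynthParams(duration_s=20.0, seed=6)
    open_sig, _ = generate_lfp(params, constant_zones(20.0))
    sig, log, _ = closed_loop_session(params, "disruption", seed=6)
    stims = log.stim_times()
    assert len(stims) > 0
    hc = sig.channels_with_role("hippocampal")[0]
    for t in stims:
        i = sig.time_to_index(t)
        delta = sig.data[hc, i] - open_sig.data[hc, i] * 0.05  # suppressed base
        assert abs(sig.data[hc, i]) > 500  # biphasic artifact present
    ctx = sig.channels_with_role("cortical")[0]
    np.testing.assert_array_equal(sig.data[ctx], open_sig.data[ctx])


def test_closed_loop_batch_log_invariants():
    """A batch of short sessions across conditions keeps every detection
    log invariant (lockout, delay ranges, condition consistency)."""
    for seed, condition in enumerate(
        ["disruption", "stim_control", "no_stim"] * 2, start=30
    ):
        params = LfpSynthParams(duration_s=20.0, seed=seed)
        _, log, _ = closed_loop_session(params, condition, seed=seed)
        stim = np.sort(log.stim_times())
        if len(stim) > 1:
            assert np.min(np.diff(stim)) >= 0.150 - 1e-9
        if condition == "no_stim":
            assert len(stim) == 0
        kept = log.entries[np.isfinite(log.entries.t_stim_s)]
        if condition == "stim_control" and len(kept):
            delays = kept.t_stim_s - kept.t_detect_s
            assert ((delays >= 0.150) & (delays <= 0.250)).all()
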