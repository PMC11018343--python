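"""Causal simulation of the real-time ripple detector and stimulator.

The detection statistic is the ripple power RP: the causal running RMS
of the ripple-band-filtered signal (Chebyshev type-II IIR, order 20,
passband 135-255 Hz, forward-only), summed over the hippocampal
channels.  A ripple is detected at the first sample where
``RP - mu(t) > f * mad(t)``, with ``mu`` and ``mad`` exponential moving
averages (span 7 s) of RP that are frozen for 50 ms after each
detection.  The same detector runs on a cortical channel; a hippocampal
detection is flagged as vetoed (a movement/chewing artifact) when a
cortical detection falls in a [-40, +1.5] ms window around it — the
1.5 ms lookahead is honored by deferring the veto decision.

Stimulation scheduling depends on the condition: immediate (1 ms fixed
round-trip latency) for disruption, a random 150-250 ms delay for the
stimulated control, none for the unstimulated control.  A 150 ms
lockout prevents stimulations closer than 150 ms: in disruption,
detections within 150 ms of a prior (non-discarded) detection are
discarded; in the stimulated control, detections whose delayed
stimulation would fall within 150 ms of the previously scheduled
stimulation are discarded.

Everything here is causal: the output at time t depends only on samples
at or before t (plus the declared 1.5 ms veto deferral), which is
verified in the test suite by truncation equivalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._kernels import ema_threshold_sweep
from .core import (
    CONDITIONS,
    ContinuousSignal,
    DetectionLog,
    EventList,
    ValidationError,
    ZoneTrace,
)
from .synth import LfpSynthParams, _generate_components, apply_stimulation, constant_zones

log = logging.getLogger("ripplecheck")


@dataclass(frozen=True)
class OnlineConfig:
    """Tunables of the simulated real-time detector."""

    band_hz: tuple[float, float] = (135.0, 255.0)
    filter_order: int = 20
    stopband_db: float = 40.0
    rms_window_s: float = 0.008
    span_s: float = 7.0
    freeze_s: float = 0.050
    warmup_s: float = 2.0
    veto_before_s: float = 0.040
    veto_after_s: float = 0.0015
    lockout_s: float = 0.150
    disruption_latency_s: float = 0.001
    delay_range_s: tuple[float, float] = (0.150, 0.250)

    def alpha(self, fs: float) -> float:
        # conventional span definition of an EMA coefficient
        return 2.0 / (self.span_s * fs + 1.0)


def design_online_filter(
    fs: float,
    band_hz: tuple[float, float] = (135.0, 255.0),
    order: int = 20,
    stopband_db: float = 40.0,
) -> np.ndarray:
    """Chebyshev type-II band-pass in second-order sections.

    ``order`` is the overall filter order (a band-pass of order 2N is
    produced from an N-th order prototype).
    """
    nyq = fs / 2.0
    lo, hi = band_hz
    if not 0 < lo < hi < nyq:
        raise ValidationError(f"band {band_hz} invalid for fs={fs}")
    if order % 2:
        raise ValidationError("band-pass order must be even")
    sos = sps.cheby2(order // 2, stopband_db, [lo, hi], btype="bandpass", fs=fs, output="sos")
    # poles of every biquad section must lie inside the unit circle
    for section in sos:
        poles = np.roots(section[3:])
        if np.any(np.abs(poles) >= 1.0):
            raise ValidationError(f"unstable filter design for fs={fs}, band={band_hz}")
    return sos


def online_band_filter(
    x: np.ndarray,
    fs: float,
    band_hz: tuple[float, float] = (135.0, 255.0),
    order: int = 20,
    stopband_db: float = 40.0,
    zi: np.ndarray | None = None,
    sos: np.ndarray | None = None,
):
    """Forward-only (causal) application of the online band-pass filter."""
    if sos is None:
        sos = design_online_filter(fs, band_hz, order, stopband_db)
    if zi is None:
        zi = np.zeros((sos.shape[0], 2))
    y, zf = sps.sosfilt(sos, np.asarray(x, dtype=float), zi=zi)
    return y, zf


def ripple_power(
    filtered: np.ndarray, fs: float, rms_window_s: float = 0.008
) -> np.ndarray:
    """Causal running RMS per channel, summed across channels.

    ``filtered`` is ``(n_channels, n)`` or ``(n,)``.  The RMS at sample
    i uses the trailing ``rms_window_s`` of samples (shorter at the
    very start).
    """
    x = np.atleast_2d(np.asarray(filtered, dtype=float))
    w = max(1, int(round(rms_window_s * fs)))
    n = x.shape[1]
    counts = np.minimum(np.arange(1, n + 1), w)
    rp = np.zeros(n)
    for ch in range(x.shape[0]):
        csum = np.cumsum(x[ch] ** 2)
        window_sum = csum.copy()
        window_sum[w:] = csum[w:] - csum[:-w]
        rp += np.sqrt(window_sum / counts)
    return rp


def _detection_delay(seed: int, det_sample: int, delay_range: tuple[float, float]) -> float:
    """Deterministic per-detection stimulation delay.

    Derived from (seed, detection sample) so a detection keeps the same
    delay when the downstream signal is modified — required for the
    incremental closed-loop simulation to be self-consistent.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, det_sample])
    return float(rng.uniform(*delay_range))


def _schedule(
    raw_samples: np.ndarray,
    ctx_samples: np.ndarray,
    fs: float,
    t0: float,
    condition: str,
    seed: int,
    config: OnlineConfig,
) -> pd.DataFrame:
    """Apply veto, lockout and stimulation scheduling to raw detections."""
    rows = []
    last_anchor = -np.inf  # last non-discarded detection (disruption lockout)
    last_stim = -np.inf  # last scheduled stimulation (stim_control lockout)
    ctx_t = t0 + ctx_samples / fs
    for s in raw_samples:
        t = t0 + s / fs
        vetoed = bool(
            np.any((ctx_t >= t - config.veto_before_s) & (ctx_t <= t + config.veto_after_s))
        )
        t_stim = np.nan
        discarded = False
        if condition == "disruption":
            if t - last_anchor < config.lockout_s:
                discarded = True
            else:
                last_anchor = t
                if not vetoed:
                    t_stim = t + config.disruption_latency_s
                    last_stim = t_stim
        elif condition == "stim_control":
            candidate = t + _detection_delay(seed, int(s), config.delay_range_s)
            if candidate - last_stim < config.lockout_s:
                discarded = True
            elif not vetoed:
                t_stim = candidate
                last_stim = candidate
        rows.append(
            {
                "t_detect_s": t,
                "vetoed": vetoed,
                "t_stim_s": t_stim,
                "discarded_by_lockout": discarded,
            }
        )
    return pd.DataFrame(
        rows, columns=["t_detect_s", "vetoed", "t_stim_s", "discarded_by_lockout"]
    )


def _raw_detections(
    signal: ContinuousSignal,
    channel_indices: list[int],
    f: float,
    config: OnlineConfig,
    sos: np.ndarray,
) -> np.ndarray:
    filtered = np.vstack(
        [online_band_filter(signal.data[ch], signal.fs, sos=sos)[0] for ch in channel_indices]
    )
    rp = ripple_power(filtered, signal.fs, config.rms_window_s)
    alpha = config.alpha(signal.fs)
    freeze_n = int(round(config.freeze_s * signal.fs))
    warm_n = int(round(config.warmup_s * signal.fs))
    det, _, _, _ = ema_threshold_sweep(
        rp, 0, len(rp), rp[0], 0.0, 0, alpha, f, freeze_n, warm_n
    )
    return det


def detect_online(
    signal: ContinuousSignal,
    f: float = 7.0,
    condition: str = "no_stim",
    seed: int = 0,
    config: OnlineConfig = OnlineConfig(),
) -> DetectionLog:
    """Simulate the real-time detector on a fixed signal.

    Requires a hippocampal channel; without a cortical channel the
    artifact veto is disabled (with a warning).
    """
    if condition not in CONDITIONS:
        raise ValidationError(f"unknown condition {condition!r}")
    if not 5.0 <= f <= 13.0:
        raise ValidationError(f"threshold multiplier f={f} outside [5, 13]")
    hc = signal.require_role("hippocampal")
    ctx = signal.channels_with_role("cortical")
    sos = design_online_filter(signal.fs, config.band_hz, config.filter_order, config.stopband_db)
    if ctx:
        ctx_det = _raw_detections(signal, [ctx[0]], f, config, sos)
    else:
        log.warning("no cortical channel: artifact veto disabled")
        ctx_det = np.empty(0, dtype=np.int64)
    raw = _raw_detections(signal, hc, f, config, sos)
    entries = _schedule(raw, ctx_det, signal.fs, signal.t0, condition, seed, config)
    return DetectionLog(entries=entries, condition=condition, f=f)


# ---------------------------------------------------------------------------
# closed-loop composition
# ---------------------------------------------------------------------------


def closed_loop_session(
    params: LfpSynthParams,
    condition: str,
    seed: int | None = None,
    f: float = 7.0,
    config: OnlineConfig = OnlineConfig(),
    zones: ZoneTrace | None = None,
    suppression_s: float = 0.050,
    suppression_floor: float = 0.05,
) -> tuple[ContinuousSignal, DetectionLog, EventList]:
    """Simulate one session with the detector in the loop.

    The base signal is generated open-loop; the detector then runs
    causally and each accepted stimulation modifies the subsequent
    signal (biphasic artifact on the hippocampal channels, plus a brief
    suppression of ongoing activity).  Because a stimulation only
    changes samples after its own time, the simulation converges by
    applying scheduled stimulations one at a time, earliest first, and
    re-running the (deterministic) causal detector: the detection
    prefix before the last applied stimulation never changes.

    In the ``no_stim`` condition the returned signal is bit-identical
    to the open-loop generation with the same seed.
    """
    if seed is None:
        seed = params.seed
    params = LfpSynthParams(**{**params.__dict__, "seed": seed})
    if zones is None:
        zones = constant_zones(params.duration_s)
    rng = np.random.default_rng(params.seed)
    hc_noise, ctx_noise, ripple_wave, truth, extents = _generate_components(
        params, zones, rng
    )
    ripple_wave = ripple_wave.copy()
    data = np.vstack([noise + ripple_wave for noise in hc_noise] + [ctx_noise])
    roles = ("hippocampal",) * params.n_hippocampal + ("cortical",)
    work = ContinuousSignal(data, fs=params.fs, channel_roles=roles)
    hc_idx = work.require_role("hippocampal")

    applied: list[int] = []
    max_iter = int(params.duration_s / max(config.lockout_s, 1e-3)) + 10
    for _ in range(max_iter):
        detlog = detect_online(work, f=f, condition=condition, seed=seed, config=config)
        stim_samples = [work.time_to_index(t) for t in np.sort(detlog.stim_times())]
        new = [s for s in stim_samples if not applied or s > applied[-1]]
        # determinism check: already-applied stimulations must reappear
        if stim_samples[: len(applied)] != applied:  # pragma: no cover
            raise RuntimeError("closed-loop simulation lost prefix stability")
        if not new:
            return work, detlog, truth
        s = new[0]
        # the stimulation terminates the ongoing burst, not just pauses it:
        # remove the remainder of any burst whose extent contains the
        # stimulation sample before applying the suppression window
        for i0, i1 in extents:
            if i0 <= s < i1:
                for ch, noise in zip(hc_idx, hc_noise):
                    work.data[ch, s:i1] = noise[s:i1]
                ripple_wave[s:i1] = 0.0
        apply_stimulation(
            work.data,
            hc_idx,
            s,
            work.fs,
            artifact_amp_uv=params.artifact_amp_uv,
            suppression_s=suppression_s,
            suppression_floor=suppression_floor,
            suppress=True,
        )
        applied.append(s)
    raise RuntimeError("closed-loop simulation did not converge")  # pragma: no cover
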