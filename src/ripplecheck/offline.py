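"""Offline sharp-wave-ripple detection on the recorded (or synthetic) LFP.

The detector band-passes the hippocampal channels in the ripple band
(140-225 Hz, zero-phase), takes the magnitude of the analytic signal,
averages across channels and smooths with a Gaussian kernel.  Candidate
events are samples where the envelope exceeds a robust data-derived
threshold ``med + 9*(Q3 - med)`` computed over the whole analyzed epoch;
each candidate is then extended to the contiguous region above a
per-event boundary threshold ``med_w + 0.4*(Q3_w - med_w)`` whose
statistics come from a 30 ms window 100-70 ms before the event.  Events
separated by less than 20 ms are merged and events shorter than 40 ms
discarded.  Because both thresholds are derived from the data, the
detector is invariant to a constant gain rescaling of the signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len
from scipy.ndimage import gaussian_filter1d

from .core import ContinuousSignal, EventList, ValidationError, ZoneTrace

log = logging.getLogger("ripplecheck")

RIPPLE_BAND_HZ = (140.0, 225.0)
MUA_BAND_HZ = (300.0, 2000.0)
SMOOTH_S = 0.015


@dataclass
class EnvelopeTrace:
    """Nonnegative envelope (uV) with its provenance."""

    env: np.ndarray
    fs: float
    band_hz: tuple[float, float] = RIPPLE_BAND_HZ
    smooth_s: float = SMOOTH_S
    channels: tuple[int, ...] = ()
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.env = np.asarray(self.env, dtype=float)
        if np.any(self.env < -1e-9):
            raise ValidationError("envelope must be nonnegative")

    @property
    def n_samples(self) -> int:
        return len(self.env)

    def time_to_index(self, t: float) -> int:
        return int(round((t - self.t0) * self.fs))

    def index_to_time(self, i: int | np.ndarray):
        return self.t0 + np.asarray(i) / self.fs


@dataclass(frozen=True)
class ThresholdSpec:
    """Robust threshold ``med + multiplier * (q3 - med)``."""

    med: float
    q3: float
    multiplier: float

    @property
    def value(self) -> float:
        return self.med + self.multiplier * (self.q3 - self.med)


def bandpass_sos(band_hz: tuple[float, float], fs: float, order: int = 4):
    """Zero-phase-ready Butterworth design; falls back to a high-pass when
    the upper edge reaches the Nyquist frequency (as for the 300-2000 Hz
    multi-unit band at 4 kHz sampling)."""
    nyq = fs / 2.0
    lo, hi = band_hz
    if lo <= 0 or lo >= nyq or hi > nyq:
        raise ValidationError(f"band {band_hz} outside (0, Nyquist={nyq}] Hz")
    if hi >= nyq * 0.999:
        return sps.butter(order, lo, btype="highpass", fs=fs, output="sos")
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def ripple_envelope(
    signal: ContinuousSignal,
    band_hz: tuple[float, float] = RIPPLE_BAND_HZ,
    smooth_s: float = SMOOTH_S,
    channels: list[int] | None = None,
) -> EnvelopeTrace:
    """Band-pass, Hilbert magnitude, channel average, Gaussian smoothing.

    ``smooth_s`` is interpreted as the standard deviation of the
    Gaussian kernel.  ``channels`` defaults to all hippocampal channels.
    """
    if channels is None:
        channels = signal.require_role("hippocampal")
    sos = bandpass_sos(band_hz, signal.fs)
    n = signal.n_samples
    env_sum = np.zeros(n)
    nfast = next_fast_len(n)
    for ch in channels:
        filtered = sps.sosfiltfilt(sos, signal.data[ch])
        analytic = sps.hilbert(filtered, N=nfast)[:n]
        env_sum += np.abs(analytic)
    env = env_sum / len(channels)
    if smooth_s > 0:
        env = gaussian_filter1d(env, sigma=smooth_s * signal.fs, mode="reflect")
    return EnvelopeTrace(
        env,
        fs=signal.fs,
        band_hz=tuple(band_hz),
        smooth_s=smooth_s,
        channels=tuple(channels),
        t0=signal.t0,
    )


def remove_stim_artifacts(
    signal: ContinuousSignal,
    stim_times_s,
    window_s: float = 0.010,
) -> ContinuousSignal:
    """Replace a 10 ms window around each stimulation by cubic interpolation.

    The interpolant is a least-squares cubic fit to ~2 ms of flanking
    samples on each side of the window (a plain 4-point cubic through
    two tight anchor pairs amplifies noise into large overshoots);
    overlapping windows are merged into one interpolation span, and
    windows clipped by the signal edge are shrunk (with a logged
    warning).  All channels are interpolated.
    """
    stim_times = np.sort(np.asarray(list(stim_times_s), dtype=float))
    out = signal.copy()
    if len(stim_times) == 0:
        return out
    if np.any(stim_times < signal.t0) or np.any(stim_times > signal.t_end):
        raise ValidationError("stimulation time outside signal span")
    half = window_s / 2.0
    n = out.n_samples
    # merge overlapping windows into spans of sample indices
    spans: list[list[int]] = []
    for t in stim_times:
        i0 = out.time_to_index(t - half)
        i1 = out.time_to_index(t + half)
        if spans and i0 <= spans[-1][1]:
            spans[-1][1] = max(spans[-1][1], i1)
        else:
            spans.append([i0, i1])
    flank = max(4, int(round(0.002 * out.fs)))  # ~2 ms of anchors per side
    for i0, i1 in spans:
        if i0 < flank or i1 > n - flank:
            log.warning("artifact window at edge of signal; shrinking")
            i0 = max(i0, flank)
            i1 = min(i1, n - flank)
            if i1 <= i0:
                continue
        anchors = np.concatenate([np.arange(i0 - flank, i0), np.arange(i1, i1 + flank)])
        fill_x = np.arange(i0, i1, dtype=float)
        for ch in range(out.n_channels):
            coeffs = np.polynomial.polynomial.polyfit(
                anchors - float(i0), out.data[ch, anchors], deg=3
            )
            out.data[ch, i0:i1] = np.polynomial.polynomial.polyval(fill_x - i0, coeffs)
    return out


def _contiguous_regions(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [i0, i1) index ranges where mask is True."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_ripples_offline(
    env: EnvelopeTrace,
    detect_multiplier: float = 9.0,
    boundary_multiplier: float = 0.4,
    pre_window_s: tuple[float, float] = (-0.100, -0.070),
    merge_gap_s: float = 0.020,
    min_duration_s: float = 0.040,
) -> EventList:
    """Detect ripple events in a smoothed ripple-band envelope.

    Epoch statistics (median, upper quartile) are computed over all
    samples of the analyzed epoch.  If a pre-event window overlaps a
    previous event it is used as-is (logged at debug level).
    """
    n = env.n_samples
    if n / env.fs < 0.2:
        raise ValidationError("epoch shorter than 200 ms")
    med = float(np.median(env.env))
    q3 = float(np.percentile(env.env, 75))
    high = ThresholdSpec(med, q3, detect_multiplier).value
    candidates = _contiguous_regions(env.env > high)
    if not candidates:
        return EventList.empty(source="offline")

    fs = env.fs
    w0 = int(round(pre_window_s[0] * fs))
    w1 = int(round(pre_window_s[1] * fs))
    raw: list[tuple[int, int]] = []
    prev_end = -1
    for c0, c1 in candidates:
        j0, j1 = c0 + w0, c0 + w1
        if j1 <= 0:
            # event too close to epoch start for a pre-window: fall back
            # to epoch statistics for the boundary threshold
            med_w, q3_w = med, q3
        else:
            j0 = max(j0, 0)
            win = env.env[j0:j1]
            if prev_end > j0:
                log.debug("pre-event window overlaps a previous event; used as-is")
            med_w = float(np.median(win))
            q3_w = float(np.percentile(win, 75))
        boundary = ThresholdSpec(med_w, q3_w, boundary_multiplier).value
        peak_idx = c0 + int(np.argmax(env.env[c0:c1]))
        above = env.env > min(boundary, high)
        # walk out from the candidate to the contiguous boundary region
        i0 = c0
        while i0 > 0 and above[i0 - 1]:
            i0 -= 1
        i1 = c1
        while i1 < n and above[i1]:
            i1 += 1
        raw.append((i0, i1))
        prev_end = i1

    # merge events separated by less than merge_gap_s
    gap_n = int(round(merge_gap_s * fs))
    merged: list[list[int]] = []
    for i0, i1 in raw:
        if merged and i0 - merged[-1][1] < gap_n:
            merged[-1][1] = max(merged[-1][1], i1)
        else:
            merged.append([i0, i1])

    min_n = int(round(min_duration_s * fs))
    starts, ends, peak_t, peak_a = [], [], [], []
    for i0, i1 in merged:
        if i1 - i0 < min_n:
            continue
        pk = i0 + int(np.argmax(env.env[i0:i1]))
        starts.append(env.index_to_time(i0))
        ends.append(env.index_to_time(i1))
        peak_t.append(env.index_to_time(pk))
        peak_a.append(float(env.env[pk]))
    return EventList(
        np.asarray(starts, dtype=float),
        np.asarray(ends, dtype=float),
        np.asarray(peak_t, dtype=float),
        np.asarray(peak_a, dtype=float),
        source="offline",
    )


def ripple_rate(
    events: EventList,
    zones: ZoneTrace,
    speed_threshold_cm_s: float = 5.0,
) -> float:
    """Event rate (Hz) restricted to immobility (speed < 5 cm/s).

    Counts events whose peak falls within an immobile zone sample and
    divides by the total immobile time.  Returns NaN (with a warning)
    when there is no immobile time — undefined, not zero.
    """
    mask = zones.immobile_mask(speed_threshold_cm_s)
    dt = zones.dt
    immobile_time = float(mask.sum() * dt)
    if immobile_time <= 0:
        log.warning("ripple_rate undefined: zero immobile time")
        return float("nan")
    if len(events) == 0:
        return 0.0
    idx = np.clip(np.searchsorted(zones.time_s, events.peak_time_s), 0, len(mask) - 1)
    n_immobile = int(mask[idx].sum())
    return n_immobile / immobile_time


def ripple_peak_amplitude(
    signal: ContinuousSignal,
    event: tuple[float, float],
    band_hz: tuple[float, float] = RIPPLE_BAND_HZ,
    smooth_s: float = SMOOTH_S,
    env: EnvelopeTrace | None = None,
) -> float:
    """Peak ripple-band envelope (uV) within ``[start, end)``.

    Pass a precomputed ``env`` to avoid re-filtering when scoring many
    events on the same signal.
    """
    start, end = event[0], event[1]
    if env is None:
        env = ripple_envelope(signal, band_hz=band_hz, smooth_s=smooth_s)
    i0 = max(0, env.time_to_index(start))
    i1 = min(env.n_samples, env.time_to_index(end))
    if i1 <= i0:
        raise ValidationError("event interval is empty or outside the signal")
    return float(np.max(env.env[i0:i1]))
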