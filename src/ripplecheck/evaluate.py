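"""Accuracy and efficacy metrics for the simulated online detector.

Online detections are matched against offline-detected (or
ground-truth) ripple intervals: an offline event is a true positive
when at least one online detection falls inside it (plus an optional
tolerance), and an online detection not inside any event counts toward
the false discovery rate.  Disruption efficacy is the mean ripple (or
multi-unit) envelope in a +20..+50 ms window after each detection,
normalized by the mean envelope in the -50..-20 ms window before it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ContinuousSignal, DetectionLog, EventList, ValidationError, ZoneTrace
from .offline import MUA_BAND_HZ, RIPPLE_BAND_HZ, remove_stim_artifacts, ripple_envelope

log = logging.getLogger("ripplecheck")

LONG_RIPPLE_THRESHOLD_S = 0.100


@dataclass
class MatchResult:
    """Online-vs-offline matching summary.

    ``tpr``/``fdr`` are NaN (flagged via ``tpr_defined``/``fdr_defined``)
    when the corresponding denominator is empty.  ``delays_ms`` holds
    the per-matched-event absolute detection delay (first matching
    detection minus event start); ``relative_delays_pct`` the delay as
    a percentage of event duration, with ``long_event`` flagging events
    longer than 100 ms.
    """

    tpr: float
    fdr: float
    n_offline: int
    n_online: int
    matched_pairs: list[tuple[int, float]] = field(default_factory=list)
    delays_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    relative_delays_pct: np.ndarray = field(default_factory=lambda: np.empty(0))
    long_event: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    @property
    def tpr_defined(self) -> bool:
        return np.isfinite(self.tpr)

    @property
    def fdr_defined(self) -> bool:
        return np.isfinite(self.fdr)

    @property
    def n_true_positive(self) -> int:
        return len(self.matched_pairs)


def _as_times(online) -> np.ndarray:
    if isinstance(online, DetectionLog):
        return online.accepted_times()
    return np.asarray(online, dtype=float)


def match_detections(
    online,
    offline: EventList,
    tolerance_s: float = 0.0,
    long_threshold_s: float = LONG_RIPPLE_THRESHOLD_S,
) -> MatchResult:
    """Match online detection times to offline ripple intervals.

    ``online`` is a :class:`DetectionLog` (its accepted detections are
    used) or a plain array of detection times.  Each online detection
    is attributed to the earliest event whose padded interval
    ``[start - tol, end + tol)`` contains it; an event's delay is taken
    from its earliest matching detection.
    """
    times = np.sort(_as_times(online))
    n_online = len(times)
    n_offline = len(offline)
    if n_offline == 0:
        log.warning("TPR undefined: empty offline event list")
    if n_online == 0:
        log.warning("FDR undefined: empty online detection list")

    matched_pairs: list[tuple[int, float]] = []
    delays, rel, is_long = [], [], []
    online_matched = np.zeros(n_online, dtype=bool)
    for ev_idx in range(n_offline):
        lo = offline.start_s[ev_idx] - tolerance_s
        hi = offline.end_s[ev_idx] + tolerance_s
        inside = np.flatnonzero((times >= lo) & (times < hi))
        if len(inside) == 0:
            continue
        first_unclaimed = [j for j in inside if not online_matched[j]]
        online_matched[inside] = True
        if not first_unclaimed:
            continue  # all its detections already claimed by an earlier event
        t_det = times[first_unclaimed[0]]
        matched_pairs.append((ev_idx, float(t_det)))
        duration = offline.end_s[ev_idx] - offline.start_s[ev_idx]
        delay = t_det - offline.start_s[ev_idx]
        delays.append(delay * 1e3)
        rel.append(100.0 * delay / duration)
        is_long.append(duration > long_threshold_s)

    tp = len(matched_pairs)
    tpr = tp / n_offline if n_offline else float("nan")
    fdr = float(np.sum(~online_matched)) / n_online if n_online else float("nan")
    return MatchResult(
        tpr=tpr,
        fdr=fdr,
        n_offline=n_offline,
        n_online=n_online,
        matched_pairs=matched_pairs,
        delays_ms=np.asarray(delays),
        relative_delays_pct=np.asarray(rel),
        long_event=np.asarray(is_long, dtype=bool),
    )


def normalized_post_detection_power(
    signal: ContinuousSignal,
    detections: DetectionLog,
    band: str | tuple[float, float] = "ripple",
    pre_window_s: tuple[float, float] = (-0.050, -0.020),
    post_window_s: tuple[float, float] = (0.020, 0.050),
    remove_artifacts: bool = True,
) -> float:
    """Session-mean ratio of post- to pre-detection band envelope.

    For every accepted detection, the mean envelope in the post window
    (+20..+50 ms) is divided by the mean in the pre window (-50..-20
    ms); the session value is the mean ratio over detections.  The
    stimulation artifact is removed by cubic interpolation around every
    stimulation time, and — for a fair comparison with disruption
    sessions — also around the detection time in stimulated-control
    sessions.  Detections too close to the epoch edges are skipped
    (logged).
    """
    if band == "ripple":
        band_hz = RIPPLE_BAND_HZ
    elif band == "mua":
        band_hz = MUA_BAND_HZ
    else:
        band_hz = tuple(band)

    det_times = detections.accepted_times()
    if remove_artifacts:
        interp_times = list(detections.stim_times())
        if detections.condition == "stim_control":
            interp_times.extend(det_times.tolist())
        if detections.condition == "disruption":
            interp_times.extend(det_times.tolist())
        clean = remove_stim_artifacts(signal, sorted(interp_times)) if interp_times else signal
    else:
        clean = signal
    env = ripple_envelope(clean, band_hz=band_hz)

    ratios = []
    n = env.n_samples
    for t in det_times:
        i_pre0 = env.time_to_index(t + pre_window_s[0])
        i_pre1 = env.time_to_index(t + pre_window_s[1])
        i_post0 = env.time_to_index(t + post_window_s[0])
        i_post1 = env.time_to_index(t + post_window_s[1])
        if i_pre0 < 0 or i_post1 > n:
            log.info("detection at %.3f s too close to epoch edge; skipped", t)
            continue
        pre = float(np.mean(env.env[i_pre0:i_pre1]))
        post = float(np.mean(env.env[i_post0:i_post1]))
        if pre <= 0:
            continue
        ratios.append(post / pre)
    if not ratios:
        log.warning("no usable detections for normalized power")
        return float("nan")
    return float(np.mean(ratios))


@dataclass(frozen=True)
class LocationStats:
    """Fractions of detections per maze zone and the reward/center bias."""

    fraction_reward: float
    fraction_center: float
    fraction_arm: float
    bias: float
    n: int


def detection_location_stats(detection_times, zones: ZoneTrace) -> LocationStats:
    """Zone fractions of detections and the reward-vs-center bias.

    ``bias = (n_reward - n_center) / n_total`` in [-1, 1].  Raises for
    zero detections (undefined, flagged).
    """
    times = _as_times(detection_times)
    if len(times) == 0:
        raise ValidationError("location stats undefined for zero detections")
    zone = zones.zone_at(times)
    n = len(times)
    n_reward = int(np.sum(zone == "reward"))
    n_center = int(np.sum(zone == "center"))
    n_arm = n - n_reward - n_center
    return LocationStats(
        fraction_reward=n_reward / n,
        fraction_center=n_center / n,
        fraction_arm=n_arm / n,
        bias=(n_reward - n_center) / n,
        n=n,
    )
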