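"""Ground-truthed synthetic LFP and synthetic radial-maze behavior.

The LFP generator produces spectrally shaped (1/f^alpha) background
noise plus transient ripple-band bursts: a sinusoidal carrier under a
Gaussian amplitude envelope.  Burst times follow a Poisson process whose
rate depends on the behavioral state (reward/immobile, center, arm run),
mirroring the empirical concentration of ripples during reward
consumption and immobility.  Every inserted burst is recorded in a
ground-truth event list whose interval is defined where the true
envelope exceeds 10% of its peak — an unambiguous reference for latency
and boundary metrics.

The behavior generators are simple stochastic agents standing in for
rats: a recency-weighted memory model for the non-match-to-sample task,
a saturating learning-curve choice model for the match-to-sample task,
and a per-transition step-learning model for the sequence task.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (
    CONDITIONS,
    ContinuousSignal,
    DetectionLog,
    EventList,
    ValidationError,
    Visit,
    VisitLog,
    ZoneTrace,
)

log = logging.getLogger("ripplecheck")

#: a Gaussian envelope is above 10% of its peak within +-GAUSS_10PCT_SIGMA sigma
GAUSS_10PCT_SIGMA = float(np.sqrt(2.0 * np.log(10.0)))  # ~2.1460


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class LfpSynthParams:
    """Parameters of the synthetic LFP generator.

    Defaults reflect the study conditions: 4 kHz sampling, ~20 uV RMS
    background noise, ripple rate ~0.5 Hz during immobile reward
    consumption and much lower while running, carrier frequencies
    150-220 Hz, durations 40-150 ms with 26% of bursts longer than
    100 ms, and peak envelopes around 160 uV.
    """

    duration_s: float = 60.0
    fs: float = 4000.0
    noise_exponent: float = 1.0
    noise_rms_uv: float = 20.0
    ripple_rate_by_state: dict[str, float] = field(
        default_factory=lambda: {"reward_immobile": 0.5, "center": 0.1, "arm_run": 0.02}
    )
    ripple_freq_range_hz: tuple[float, float] = (150.0, 220.0)
    ripple_duration_range_s: tuple[float, float] = (0.04, 0.15)
    long_fraction: float = 0.26
    long_threshold_s: float = 0.100
    ripple_amp_range_uv: tuple[float, float] = (110.0, 210.0)
    artifact_amp_uv: float = 1000.0
    min_gap_s: float = 0.250
    n_hippocampal: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration must be positive")
        if any(r < 0 for r in self.ripple_rate_by_state.values()):
            raise ValidationError("ripple rates must be nonnegative")
        lo, hi = self.ripple_freq_range_hz
        if not (0 < lo <= hi < self.fs / 2):
            raise ValidationError("ripple frequency range must lie within (0, fs/2)")
        if self.n_hippocampal < 1:
            raise ValidationError("need at least one hippocampal channel")


@dataclass
class AgentParams:
    """Parameters of the behavioral agents.

    ``memory_recency_weights`` gives, per instruction position (1 =
    instructed first, furthest back in time), the probability the agent
    still recalls that arm at test — increasing weights yield the
    recency-biased error pattern seen in rats.  ``learning_rate`` and
    ``asymptote`` shape the saturating per-trial correct-choice
    probability of the MTS agent.  ``per_transition_onset`` gives, per
    SEQ transition, the global visit index at which its correct-choice
    probability steps from ``p_chance`` to ``p_learned``.
    """

    task: str = "NMTS"
    n_trials: int | None = None
    memory_recency_weights: tuple[float, float, float, float] = (0.75, 0.85, 0.93, 0.98)
    learning_rate: float = 0.45
    asymptote: float = 0.93
    p_start: float = 0.40
    stereotypy_strength: float = 0.75
    per_transition_onset: tuple[int, int, int, int] = (150, 150, 150, 150)
    p_chance: float = 0.5
    p_learned: float = 0.90
    run1_visits: int = 220
    run2_visits: int = 220
    visit_duration_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            *self.memory_recency_weights,
            self.asymptote,
            self.p_start,
            self.p_chance,
            self.p_learned,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# zone traces
# ---------------------------------------------------------------------------


def constant_zones(
    duration_s: float, zone: str = "reward", speed_cm_s: float = 0.0, fs: float = 25.0
) -> ZoneTrace:
    """A trivial zone trace: the whole epoch in one zone at one speed."""
    n = max(2, int(round(duration_s * fs)))
    t = np.arange(n) / fs
    return ZoneTrace(t, np.full(n, zone, dtype=object), np.full(n, speed_cm_s))


def cycling_zones(
    duration_s: float,
    fs: float = 25.0,
    dwell_s: dict[str, float] | None = None,
    run_speed_cm_s: float = 40.0,
) -> ZoneTrace:
    """Cycle reward (immobile) -> arm (run) -> center -> arm (run) -> ...

    A stylized trial structure: long immobile reward consumption bouts
    separated by running on the arms with brief pauses on the center.
    """
    dwell = {"reward": 8.0, "arm": 2.0, "center": 2.0}
    if dwell_s:
        dwell.update(dwell_s)
    order = ["reward", "arm", "center", "arm"]
    n = max(2, int(round(duration_s * fs)))
    t = np.arange(n) / fs
    zone = np.empty(n, dtype=object)
    speed = np.zeros(n)
    pos = 0.0
    k = 0
    while pos < duration_s:
        z = order[k % len(order)]
        sl = (t >= pos) & (t < pos + dwell[z])
        zone[sl] = z
        speed[sl] = run_speed_cm_s if z == "arm" else 0.0
        pos += dwell[z]
        k += 1
    zone[zone == None] = "reward"  # noqa: E711 - trailing partial segment
    return ZoneTrace(t, zone, speed)


# ---------------------------------------------------------------------------
# LFP synthesis
# ---------------------------------------------------------------------------


def colored_noise(
    n: int, fs: float, exponent: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, scaled to ``rms``.

    The spectrum is flattened below 1 Hz so the variance stays finite.
    """
    white = rng.standard_normal(n)
    if exponent == 0 or rms == 0:
        out = white
    else:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, 1.0 / fs)
        shaping = np.ones_like(freqs)
        nz = freqs > 0
        shaping[nz] = np.maximum(freqs[nz], 1.0) ** (-exponent / 2.0)
        shaping[0] = 0.0
        out = np.fft.irfft(spec * shaping, n)
    sd = out.std()
    if sd > 0:
        out = out * (rms / sd)
    return out


def _draw_ripple_times(
    params: LfpSynthParams, zones: ZoneTrace, rng: np.random.Generator
) -> np.ndarray:
    """State-dependent Poisson event times with a minimum gap.

    The minimum-gap rejection acts as a non-paralyzable dead time, so
    the candidate rate is inflated by 1/(1 - lambda*dead) per state to
    keep the realized marginal rate equal to the requested one.
    """
    rates = params.ripple_rate_by_state
    dead = params.min_gap_s + params.ripple_duration_range_s[1]

    def compensated(lam: float) -> float:
        return lam / max(1.0 - lam * dead, 0.1)

    lam_max = max((compensated(r) for r in rates.values()), default=0.0)
    if lam_max <= 0:
        return np.empty(0)
    # homogeneous candidates at the max compensated rate, thinned locally
    n_cand = rng.poisson(lam_max * params.duration_s)
    cand = np.sort(rng.uniform(0.0, params.duration_s, size=n_cand))
    state = zones.state_at(cand)
    local = np.array([compensated(rates.get(s, 0.0)) for s in state])
    keep = rng.uniform(size=n_cand) < local / lam_max
    times = cand[keep]
    # enforce the minimum inter-ripple gap and edge margins
    margin = params.ripple_duration_range_s[1] / 2 + 0.05
    accepted: list[float] = []
    for t in times:
        if t < margin or t > params.duration_s - margin:
            continue
        if accepted and t - accepted[-1] < dead:
            continue
        accepted.append(t)
    return np.asarray(accepted)


def _generate_components(
    params: LfpSynthParams, zones: ZoneTrace, rng: np.random.Generator
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray, EventList, list[tuple[int, int]]]:
    """Noise per hippocampal channel, cortical noise, shared ripple wave,
    ground truth, and the sample extent of each inserted burst."""
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs
    centers = _draw_ripple_times(params, zones, rng)

    ripple_wave = np.zeros(n)
    extents: list[tuple[int, int]] = []
    starts, ends, peaks_t, peaks_a = [], [], [], []
    lo_d, hi_d = params.ripple_duration_range_s
    for c in centers:
        if rng.uniform() < params.long_fraction:
            dur = rng.uniform(max(lo_d, params.long_threshold_s), hi_d)
        else:
            dur = rng.uniform(lo_d, min(hi_d, params.long_threshold_s))
        sigma = dur / (2.0 * GAUSS_10PCT_SIGMA)
        amp = rng.uniform(*params.ripple_amp_range_uv)
        freq = rng.uniform(*params.ripple_freq_range_hz)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        i0 = max(0, int((c - 4 * sigma) * params.fs))
        i1 = min(n, int((c + 4 * sigma) * params.fs) + 1)
        tt = t[i0:i1] - c
        ripple_wave[i0:i1] += (
            amp * np.exp(-0.5 * (tt / sigma) ** 2) * np.cos(2 * np.pi * freq * tt + phase)
        )
        extents.append((i0, i1))
        starts.append(c - dur / 2.0)
        ends.append(c + dur / 2.0)
        peaks_t.append(c)
        peaks_a.append(amp)

    truth = EventList(
        np.asarray(starts),
        np.asarray(ends),
        np.asarray(peaks_t),
        np.asarray(peaks_a),
        source="ground_truth",
    )
    hc_noise = [
        colored_noise(n, params.fs, params.noise_exponent, params.noise_rms_uv, rng)
        for _ in range(params.n_hippocampal)
    ]
    ctx_noise = colored_noise(n, params.fs, params.noise_exponent, params.noise_rms_uv, rng)
    return hc_noise, ctx_noise, ripple_wave, truth, extents


def generate_lfp(
    params: LfpSynthParams, zones: ZoneTrace | None = None
) -> tuple[ContinuousSignal, EventList]:
    """Generate a multichannel LFP and its ground-truth ripple events.

    The hippocampal channels share the ripple bursts (as electrodes in
    the same structure would) on top of independent background noise;
    the cortical channel carries independent noise only.  Ground-truth
    intervals span where each burst's true envelope exceeds 10% of its
    peak, i.e. exactly the drawn duration centered on the drawn time.
    """
    if zones is None:
        zones = constant_zones(params.duration_s)
    if zones.time_s[-1] < params.duration_s - 1.0:
        raise ValidationError("zone trace does not span the requested duration")
    rng = np.random.default_rng(params.seed)
    hc_noise, ctx_noise, ripple_wave, truth, _ = _generate_components(params, zones, rng)
    data = np.vstack([noise + ripple_wave for noise in hc_noise] + [ctx_noise])
    roles = ("hippocampal",) * params.n_hippocampal + ("cortical",)
    return ContinuousSignal(data, fs=params.fs, channel_roles=roles), truth


# ---------------------------------------------------------------------------
# closed-loop stimulation effects
# ---------------------------------------------------------------------------


def _suppression_profile(n_window: int, n_recovery: int, floor: float) -> np.ndarray:
    """Multiplicative amplitude factor after a stimulation.

    Drops immediately to ``floor``, holds there for the suppression
    window, then recovers smoothly (raised cosine) to 1 over the
    recovery span — a phenomenological model of the transient network
    silencing that follows commissural stimulation; the depth is a free
    synthetic parameter, not an empirical claim.
    """
    hold = np.full(n_window, floor)
    x = np.arange(1, n_recovery + 1) / max(n_recovery, 1)
    ramp = floor + (1.0 - floor) * 0.5 * (1.0 - np.cos(np.pi * x))
    return np.concatenate([hold, ramp])


def apply_stimulation(
    data: np.ndarray,
    channel_indices: list[int],
    stim_sample: int,
    fs: float,
    artifact_amp_uv: float = 1000.0,
    suppression_s: float = 0.050,
    suppression_floor: float = 0.05,
    recovery_s: float = 0.020,
    suppress: bool = True,
) -> None:
    """In-place biphasic artifact (0.2 ms per phase) plus optional suppression."""
    n = data.shape[1]
    if not 0 <= stim_sample < n:
        raise ValidationError("stimulation time outside signal span")
    phase_n = max(1, int(round(0.0002 * fs)))
    if suppress:
        profile = _suppression_profile(
            int(round(suppression_s * fs)), int(round(recovery_s * fs)), suppression_floor
        )
        j1 = min(n, stim_sample + len(profile))
        for ch in channel_indices:
            data[ch, stim_sample:j1] *= profile[: j1 - stim_sample]
    for ch in channel_indices:
        j1 = min(n, stim_sample + phase_n)
        data[ch, stim_sample:j1] += artifact_amp_uv
        j2 = min(n, stim_sample + 2 * phase_n)
        data[ch, j1:j2] -= artifact_amp_uv


def apply_closed_loop(
    signal: ContinuousSignal,
    detections: DetectionLog,
    condition: str | None = None,
    artifact_amp_uv: float = 1000.0,
    suppression_s: float = 0.050,
    suppression_floor: float = 0.05,
) -> ContinuousSignal:
    """Insert stimulation artifacts and post-stimulation suppression.

    At every stimulation time a large biphasic transient is added on the
    hippocampal channels, followed by a brief multiplicative suppression
    of ongoing activity (default 50 ms).  In the delayed-stimulation
    control the triggering ripple is left intact simply because the
    stimulation arrives 150-250 ms after detection, by which time the
    ripple is over.  With no stimulations the signal is returned
    unchanged (a copy).
    """
    if condition is None:
        condition = detections.condition
    out = signal.copy()
    hc = out.require_role("hippocampal")
    for t_stim in detections.stim_times():
        if not signal.t0 <= t_stim < signal.t_end:
            raise ValidationError(f"stimulation at {t_stim} s outside signal span")
        apply_stimulation(
            out.data,
            hc,
            out.time_to_index(t_stim),
            out.fs,
            artifact_amp_uv=artifact_amp_uv,
            suppression_s=suppression_s,
            suppression_floor=suppression_floor,
            suppress=True,
        )
    return out


# ---------------------------------------------------------------------------
# behavioral agents
# ---------------------------------------------------------------------------

_RING8 = 8


def _nmts_session(params: AgentParams, rng: np.random.Generator) -> VisitLog:
    n_trials = params.n_trials or 15
    trials: list[list[Visit]] = []
    instructed_arms: list[list[int]] = []
    t = 0.0
    dt = params.visit_duration_s
    for _ in range(n_trials):
        instructed = list(rng.choice(np.arange(1, _RING8 + 1), size=4, replace=False))
        instructed_arms.append([int(a) for a in instructed])
        visits = []
        for arm in instructed:
            visits.append(Visit(int(arm), "instruction", True, t, t + dt * 0.8))
            t += dt
        complement = [a for a in range(1, _RING8 + 1) if a not in instructed]
        # arms the agent believes it has not yet visited: complement plus
        # any instructed arm it fails to recall (recency-weighted recall)
        forgotten = [
            arm
            for j, arm in enumerate(instructed)
            if rng.uniform() >= params.memory_recency_weights[j]
        ]
        candidates = complement + forgotten
        to_visit = set(complement)
        order = list(rng.permutation(candidates))
        for arm in order:
            correct = arm in to_visit
            visits.append(Visit(int(arm), "test", bool(correct), t, t + dt * 0.8))
            t += dt
            if not correct:
                break  # trial ends at the first erroneous visit
            to_visit.discard(arm)
            if not to_visit:
                break
        trials.append(visits)
        t += 90.0  # inter-trial interval
    return VisitLog(
        task="NMTS",
        session_id=f"nmts-{params.seed}",
        condition="no_stim",
        trials=trials,
        session_config={"instructed_arms": instructed_arms},
    )


def _mts_bait_set(rng: np.random.Generator) -> list[int]:
    """A 4-arm bait set, excluding configurations of 4 adjacent arms."""
    from .behavior import classify_arm_configuration

    while True:
        arms = sorted(int(a) for a in rng.choice(np.arange(1, 9), size=4, replace=False))
        if classify_arm_configuration(arms) != "all_adjacent":
            return arms


def _mts_session(params: AgentParams, rng: np.random.Generator) -> VisitLog:
    n_trials = params.n_trials or 25
    baited = _mts_bait_set(rng)
    # fixed per-session stereotyped collection order for "correct" choices
    collect_order = list(rng.permutation(baited))
    trials: list[list[Visit]] = []
    t = 0.0
    dt = params.visit_duration_s
    for trial_idx in range(n_trials):
        p = params.asymptote - (params.asymptote - params.p_start) * np.exp(
            -params.learning_rate * trial_idx
        )
        remaining = set(baited)
        visits = []
        guard = 0
        while remaining and guard < 60:
            guard += 1
            if rng.uniform() < p:
                # correct choice: usually the stereotyped next bait,
                # sometimes any remaining bait (rats are not fully rigid)
                if rng.uniform() < params.stereotypy_strength:
                    arm = next(a for a in collect_order if a in remaining)
                else:
                    arm = int(rng.choice(sorted(remaining)))
            else:
                arm = int(rng.integers(1, 9))
            correct = arm in remaining
            visits.append(Visit(int(arm), "free", bool(correct), t, t + dt * 0.8))
            t += dt
            remaining.discard(arm)
        trials.append(visits)
        t += 60.0
    return VisitLog(
        task="MTS",
        session_id=f"mts-{params.seed}",
        condition="no_stim",
        trials=trials,
        session_config={"baited_arms": baited, "collect_order": [int(a) for a in collect_order]},
    )


def _seq_arms_and_order(rng: np.random.Generator) -> tuple[list[int], list[int]]:
    """4 positions on the 12-ring and a crossing (non-circular) cyclic order."""
    positions = sorted(int(p) for p in rng.choice(np.arange(1, 13), size=4, replace=False))
    while True:
        order = [positions[0]] + [int(a) for a in rng.permutation(positions[1:])]
        ranks = [positions.index(a) for a in order]
        steps = [(ranks[(i + 1) % 4] - ranks[i]) % 4 for i in range(4)]
        if not (all(s == 1 for s in steps) or all(s == 3 for s in steps)):
            return positions, order


def _seq_session(params: AgentParams, rng: np.random.Generator) -> VisitLog:
    positions, order = _seq_arms_and_order(rng)
    successor = {order[i]: order[(i + 1) % 4] for i in range(4)}
    onset = {arm: int(params.per_transition_onset[i]) for i, arm in enumerate(order)}
    trials: list[list[Visit]] = []
    t = 0.0
    dt = params.visit_duration_s
    current = order[0]
    visit_idx = 0
    for phase, n_visits in (("run1", params.run1_visits), ("run2", params.run2_visits)):
        visits = []
        for _ in range(n_visits):
            target = successor[current]
            p = params.p_learned if visit_idx >= onset[current] else params.p_chance
            if rng.uniform() < p:
                arm = target
            else:
                arm = int(rng.choice([a for a in positions if a not in (current, target)]))
            visits.append(Visit(arm, phase, bool(arm == target), t, t + dt * 0.8))
            t += dt
            current = arm
            visit_idx += 1
        trials.append(visits)
        t += 600.0  # intervening rest epoch
    return VisitLog(
        task="SEQ",
        session_id=f"seq-{params.seed}",
        condition="no_stim",
        trials=trials,
        session_config={
            "arm_positions": positions,
            "sequence": order,
            "transition_onsets": {str(a): onset[a] for a in order},
        },
    )


def generate_session_behavior(params: AgentParams) -> VisitLog:
    """Generate one synthetic behavioral session for the given task.

    The returned log's ``session_config`` carries the generating truth
    (instructed arms, bait set, or sequence and per-transition learning
    onsets) so downstream estimators can be scored against it.
    """
    rng = np.random.default_rng(params.seed)
    if params.task == "NMTS":
        return _nmts_session(params, rng)
    if params.task == "MTS":
        return _mts_session(params, rng)
    if params.task == "SEQ":
        return _seq_session(params, rng)
    raise ValidationError(f"unknown task {params.task!r}")


def with_condition(visits: VisitLog, condition: str, session_id: str | None = None) -> VisitLog:
    """Relabel a generated session with an experimental condition."""
    if condition not in CONDITIONS:
        raise ValidationError(f"unknown condition {condition!r}")
    return VisitLog(
        task=visits.task,
        session_id=session_id or visits.session_id,
        condition=condition,
        trials=visits.trials,
        session_config=visits.session_config,
    )
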