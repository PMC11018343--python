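"""Task-performance metrics for the three radial-maze paradigms.

NMTS (non-match-to-sample): per-trial performance, correct test-phase
visits, and — for error trials — the instruction-order number of the
wrongly revisited arm (1 = instructed first, i.e. furthest back in
time; means below chance level 2.5 indicate recency-biased forgetting).

MTS (match-to-sample): final-10-trial mean visits and error-free
fraction, the learning trial (first trial after three consecutive
correct trials), a Levenshtein-similarity stereotypy index with a
within-trial shuffle null, a circular-search score with the same null,
and the adjacency classification of the baited 4-arm configuration.

SEQ (spatial sequence): moving-average visit performance, 5-visit
product sequence performance, and kernel-smoothed binomial learning
visits, overall and per arm-arm transition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .core import ValidationError, Visit, VisitLog

log = logging.getLogger("ripplecheck")


# ---------------------------------------------------------------------------
# edit distance and stereotypy
# ---------------------------------------------------------------------------


def levenshtein(a, b) -> int:
    """Minimum number of single-symbol insertions, deletions and
    substitutions turning sequence ``a`` into ``b``.

    Standard two-row dynamic program; symmetric and a metric on
    sequences.  Accepts strings or sequences of hashable symbols.
    """
    a, b = list(a), list(b)
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            cur[j] = min(
                prev[j] + 1,  # deletion
                cur[j - 1] + 1,  # insertion
                prev[j - 1] + (ca != cb),  # substitution
            )
        prev = cur
    return prev[-1]


def similarity(a, b) -> float:
    """One minus the normalized Levenshtein distance, in [0, 1]."""
    a, b = list(a), list(b)
    longest = max(len(a), len(b))
    if longest == 0:
        raise ValidationError("similarity undefined for two empty sequences")
    return 1.0 - levenshtein(a, b) / longest


def _mean_pairwise_similarity(strings: list[list]) -> float:
    n = len(strings)
    total = 0.0
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += similarity(strings[i], strings[j])
            count += 1
    return total / count


def stereotypy_index(visit_strings: list) -> float:
    """Mean pairwise similarity between the visit strings of all trial pairs."""
    strings = [list(s) for s in visit_strings]
    if len(strings) < 2:
        raise ValidationError("stereotypy index needs at least 2 trials")
    return _mean_pairwise_similarity(strings)


def shuffle_z(
    visit_strings: list,
    statistic,
    n_shuffles: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Observed statistic and its z-score against a within-trial shuffle null.

    The null randomizes the visit order independently within each trial
    ``n_shuffles`` times and recomputes the statistic.
    """
    strings = [list(s) for s in visit_strings]
    observed = statistic(strings)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuffled = [list(rng.permutation(s)) for s in strings]
        null[k] = statistic(shuffled)
    sd = null.std(ddof=1)
    if sd == 0:
        log.warning("degenerate shuffle null (zero variance)")
        return observed, float("nan")
    return observed, float((observed - null.mean()) / sd)


def stereotypy_z(
    visit_strings: list, n_shuffles: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Stereotypy index and its shuffle-null z-score."""
    return shuffle_z(visit_strings, _mean_pairwise_similarity, n_shuffles, seed)


# ---------------------------------------------------------------------------
# NMTS
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NmtsTrialMetrics:
    performance: int  # 1 iff the whole test phase is error-free
    correct_visits: int  # correct test visits before the first error (<= 4)
    error_order_number: int | None  # 1 = first-instructed; None if no error


def nmts_metrics(visits: VisitLog) -> list[NmtsTrialMetrics]:
    """Per-trial NMTS metrics from a validated visit log."""
    if visits.task != "NMTS":
        raise ValidationError("nmts_metrics requires an NMTS log")
    out = []
    for ti, trial in enumerate(visits.trials):
        instructed = [v.arm for v in trial if v.phase == "instruction"]
        test = [v for v in trial if v.phase == "test"]
        correct = 0
        error_order = None
        performance = 1
        for v in test:
            if v.correct:
                correct += 1
                continue
            performance = 0
            if v.arm not in instructed:
                raise ValidationError(
                    f"trial {ti}: error visit to arm {v.arm} outside the "
                    "instruction set — malformed log"
                )
            error_order = instructed.index(v.arm) + 1
            break
        if performance and correct != 4:
            performance = 0  # incomplete trial without error: not a success
        out.append(NmtsTrialMetrics(performance, correct, error_order))
    return out


def nmts_session_summary(visits: VisitLog) -> dict[str, float]:
    per_trial = nmts_metrics(visits)
    orders = [m.error_order_number for m in per_trial if m.error_order_number]
    return {
        "trial_performance": float(np.mean([m.performance for m in per_trial])),
        "correct_visits_test": float(np.mean([m.correct_visits for m in per_trial])),
        "error_order_number": float(np.mean(orders)) if orders else float("nan"),
    }


# ---------------------------------------------------------------------------
# MTS
# ---------------------------------------------------------------------------


def _mts_trial_correct(trial: list[Visit], baited: set[int]) -> bool:
    arms = [v.arm for v in trial]
    if set(arms) != baited or len(arms) != 4:
        return False
    return all(v.correct for v in trial)


@dataclass(frozen=True)
class MtsSessionMetrics:
    final10_mean_visits: float
    final10_performance: float
    learning_trial: int | None  # 1-based; first trial after 3 consecutive correct
    trial_correct: list[bool]
    visits_per_trial: list[int]


def mts_metrics(visits: VisitLog, final_trials: int = 10) -> MtsSessionMetrics:
    """Session metrics for a match-to-sample log.

    A trial is correct when the four baited arms are each collected
    exactly once with no visit to an unbaited arm and no revisit, i.e.
    exactly four visits, all correct.
    """
    if visits.task != "MTS":
        raise ValidationError("mts_metrics requires an MTS log")
    baited = set(visits.session_config.get("baited_arms", ()))
    if not baited:
        # fall back: the arms collected correctly in the log
        baited = {v.arm for v in visits.visits() if v.correct}
    if len(baited) != 4:
        raise ValidationError("MTS session must have a 4-arm bait set")
    correct = [_mts_trial_correct(t, baited) for t in visits.trials]
    n_visits = [len(t) for t in visits.trials]
    final_c = correct[-final_trials:]
    final_v = n_visits[-final_trials:]
    learning_trial = None
    for i in range(len(correct) - 2):
        if correct[i] and correct[i + 1] and correct[i + 2]:
            learning_trial = i + 4  # 1-based trial following the streak
            break
    return MtsSessionMetrics(
        final10_mean_visits=float(np.mean(final_v)),
        final10_performance=float(np.mean(final_c)),
        learning_trial=learning_trial,
        trial_correct=correct,
        visits_per_trial=n_visits,
    )


def classify_arm_configuration(baited) -> str:
    """Adjacency class of a 4-arm subset of the 8-arm ring.

    The class is read off the multiset of runs of consecutive arms
    (arm 1 adjacent to arm 8): {2,2} -> IIa, {2,1,1} -> IIb, {3,1} ->
    III, {1,1,1,1} -> IV_no_neighbors, {4} -> all_adjacent (such
    configurations were excluded from sessions).
    """
    arms = sorted(set(int(a) for a in baited))
    if len(arms) != 4 or any(not 1 <= a <= 8 for a in arms):
        raise ValidationError("configuration must be a 4-subset of arms 1..8")
    present = [a in arms for a in range(1, 9)]
    # count runs on the ring: start from a gap to avoid splitting a run
    # (a 4-subset of 8 always leaves at least one gap)
    start = next(i for i in range(8) if not present[i])
    runs = []
    run = 0
    for k in range(1, 9):
        if present[(start + k) % 8]:
            run += 1
        elif run:
            runs.append(run)
            run = 0
    if run:
        runs.append(run)
    key = tuple(sorted(runs, reverse=True))
    return {
        (2, 2): "IIa",
        (2, 1, 1): "IIb",
        (3, 1): "III",
        (1, 1, 1, 1): "IV_no_neighbors",
        (4,): "all_adjacent",
    }[key]


def _circularity_score(strings: list[list]) -> float:
    """Max over direction of the fraction of transitions stepping to the
    nearest remaining arm in that direction on the 8-ring.

    This score is this package's own construction; the underlying
    behavior (searching arms in clockwise/counterclockwise order) is a
    known radial-maze strategy, but the score formula is not taken from
    any published source and is labelled accordingly in outputs.
    """
    counts = {+1: 0, -1: 0}
    total = 0
    for s in strings:
        arms = list(s)
        for i in range(len(arms) - 1):
            remaining = set(arms[i + 1 :])
            remaining.discard(arms[i])
            if not remaining:
                continue
            total += 1
            for direction in (+1, -1):
                for step in range(1, 8):
                    candidate = (arms[i] - 1 + direction * step) % 8 + 1
                    if candidate in remaining:
                        if candidate == arms[i + 1]:
                            counts[direction] += 1
                        break
    if total == 0:
        raise ValidationError("circularity undefined: fewer than 2 visits per trial")
    return max(counts[+1], counts[-1]) / total


def circularity_z(
    visits: VisitLog, n_shuffles: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Circular-search score of an MTS session and its shuffle-null z."""
    strings = [[v.arm for v in t] for t in visits.trials]
    return shuffle_z(strings, _circularity_score, n_shuffles, seed)


def mts_visit_strings(visits: VisitLog, final_trials: int = 10) -> list[list[int]]:
    """Arm-visit strings of the final trials, for stereotypy analysis."""
    return [[v.arm for v in t] for t in visits.trials[-final_trials:]]


# ---------------------------------------------------------------------------
# SEQ
# ---------------------------------------------------------------------------


@dataclass
class SeqPerformance:
    outcomes: np.ndarray  # binary, merged run1+run2, first <=400 visits
    visit_performance: np.ndarray  # moving average, window 50
    sequence_performance: np.ndarray  # trailing 5-visit product (NaN while warming)
    final_visit_performance: float  # mean outcome over the final 100 visits
    final_sequence_performance: float  # mean 5-visit product over the final 100


def seq_outcomes(
    visits: VisitLog,
    min_run1_visits: int = 150,
    max_visits: int = 400,
) -> np.ndarray:
    """Binary outcome sequence of a SEQ session.

    Sessions with fewer than 150 visits in the first run epoch are
    excluded (raises ValidationError, flagged); run epochs are merged
    and only the first 400 visits are analyzed.
    """
    if visits.task != "SEQ":
        raise ValidationError("seq analysis requires a SEQ log")
    run1 = [v for v in visits.visits() if v.phase == "run1"]
    if len(run1) < min_run1_visits:
        raise ValidationError(
            f"session excluded: only {len(run1)} visits in run 1 (<{min_run1_visits})"
        )
    merged = [v for v in visits.visits() if v.phase in ("run1", "run2")]
    outcomes = np.array([int(v.correct) for v in merged], dtype=float)
    return outcomes[:max_visits]


def seq_performance(
    outcomes: np.ndarray,
    window: int = 5,
    moving_average_window: int = 50,
    final_visits: int = 100,
) -> SeqPerformance:
    """Visit and sequence performance series from a binary outcome sequence."""
    outcomes = np.asarray(outcomes, dtype=float)
    n = len(outcomes)
    # trailing moving average of single-visit outcomes
    vp = np.full(n, np.nan)
    csum = np.concatenate([[0.0], np.cumsum(outcomes)])
    for i in range(n):
        j = max(0, i - moving_average_window + 1)
        vp[i] = (csum[i + 1] - csum[j]) / (i + 1 - j)
    # product over the trailing 5-visit window
    sp = np.full(n, np.nan)
    for i in range(window - 1, n):
        sp[i] = float(np.prod(outcomes[i - window + 1 : i + 1]))
    final = slice(max(0, n - final_visits), n)
    sp_final = sp[final]
    return SeqPerformance(
        outcomes=outcomes,
        visit_performance=vp,
        sequence_performance=sp,
        final_visit_performance=float(np.mean(outcomes[final])),
        final_sequence_performance=float(np.nanmean(sp_final)),
    )


def smoothed_learning_curve(
    outcomes: np.ndarray,
    positions: np.ndarray | None = None,
    bandwidth: float = 50.0,
):
    """Gaussian-kernel smoothed success count and effective n per visit.

    The kernel (sigma = ``bandwidth`` visits) is truncated at the
    sequence edges and renormalized implicitly: the effective n at each
    evaluation point is the total kernel mass over observed visits.
    Returns ``(k_eff, n_eff, p_smooth)`` arrays aligned to ``positions``.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    if positions is None:
        positions = np.arange(len(outcomes), dtype=float)
    positions = np.asarray(positions, dtype=float)
    diff = positions[None, :] - positions[:, None]
    w = np.exp(-0.5 * (diff / bandwidth) ** 2)
    n_eff = w.sum(axis=1)
    k_eff = w @ outcomes
    return k_eff, n_eff, k_eff / n_eff


def learning_visit(
    outcomes: np.ndarray,
    positions: np.ndarray | None = None,
    bandwidth: float = 50.0,
    alpha: float = 0.01,
    chance: float = 0.5,
    sustained: bool = True,
) -> int | None:
    """Visit index at which smoothed performance is significantly above chance.

    At every visit the smoothed success count (rounded) is tested
    against a one-sided exact binomial with the rounded effective n.
    With ``sustained=True`` (default) the learning visit is the first
    visit from which the criterion holds through the end of the
    session; with ``sustained=False`` it is the literal first crossing.
    Returns the *position* (global visit index) or None if the
    criterion is never met.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    if positions is None:
        positions = np.arange(len(outcomes), dtype=float)
    if len(outcomes) < 1:
        return None
    k_eff, n_eff, _ = smoothed_learning_curve(outcomes, positions, bandwidth)
    k = np.round(k_eff).astype(int)
    n = np.maximum(np.round(n_eff).astype(int), 1)
    k = np.minimum(k, n)
    pvals = spstats.binom.sf(k - 1, n, chance)  # P(X >= k) under chance
    met = pvals < alpha
    if not met.any():
        return None
    if not sustained:
        return int(positions[int(np.argmax(met))])
    # first index from which the criterion holds through session end
    held_from = len(met)
    for i in range(len(met) - 1, -1, -1):
        if met[i]:
            held_from = i
        else:
            break
    if held_from == len(met):
        return None
    return int(positions[held_from])


@dataclass
class TransitionLearning:
    learning_visits: dict[int, int | None]  # keyed by from-arm
    spread: float | None  # max - min over learned transitions; None if < 2 learned


def transition_learning(
    visits: VisitLog,
    bandwidth: float = 50.0,
    alpha: float = 0.01,
    chance: float = 0.5,
    min_run1_visits: int = 150,
    max_visits: int = 400,
    sustained: bool = True,
) -> TransitionLearning:
    """Per-transition learning visits and the slow-minus-fast spread.

    A visit is an opportunity for the transition leaving the arm the
    animal was on before that visit; outcomes are indexed by global
    visit number so per-transition learning visits are comparable.
    """
    if visits.task != "SEQ":
        raise ValidationError("transition_learning requires a SEQ log")
    run1 = [v for v in visits.visits() if v.phase == "run1"]
    if len(run1) < min_run1_visits:
        raise ValidationError("session excluded: too few visits in run 1")
    merged = [v for v in visits.visits() if v.phase in ("run1", "run2")][:max_visits]
    sequence = visits.session_config.get("sequence")
    if not sequence:
        raise ValidationError("SEQ session_config must provide the correct sequence")
    start_arm = sequence[0]
    from_arms = [start_arm] + [v.arm for v in merged[:-1]]
    per_transition: dict[int, tuple[list[float], list[float]]] = {
        a: ([], []) for a in sequence
    }
    for global_idx, (src, v) in enumerate(zip(from_arms, merged)):
        if src in per_transition:
            pos, out = per_transition[src]
            pos.append(float(global_idx))
            out.append(float(v.correct))
    learning: dict[int, int | None] = {}
    for arm, (pos, out) in per_transition.items():
        if len(out) == 0:
            learning[arm] = None
            continue
        learning[arm] = learning_visit(
            np.asarray(out),
            positions=np.asarray(pos),
            bandwidth=bandwidth,
            alpha=alpha,
            chance=chance,
            sustained=sustained,
        )
    learned = [lv for lv in learning.values() if lv is not None]
    spread = float(max(learned) - min(learned)) if len(learned) >= 2 else None
    return TransitionLearning(learning_visits=learning, spread=spread)


# ---------------------------------------------------------------------------
# session-level dispatch
# ---------------------------------------------------------------------------


def session_metrics(visits: VisitLog, n_shuffles: int = 2000, seed: int = 0) -> dict:
    """All applicable metrics for one session, keyed by metric name."""
    if visits.task == "NMTS":
        return nmts_session_summary(visits)
    if visits.task == "MTS":
        m = mts_metrics(visits)
        strings = mts_visit_strings(visits)
        idx, z = stereotypy_z(strings, n_shuffles=n_shuffles, seed=seed)
        _, cz = circularity_z(visits, n_shuffles=n_shuffles, seed=seed)
        return {
            "final10_visits": m.final10_mean_visits,
            "final10_performance": m.final10_performance,
            "learning_trial": float(m.learning_trial) if m.learning_trial else float("nan"),
            "stereotypy_index": idx,
            "stereotypy_z": z,
            "circularity_z": cz,
        }
    if visits.task == "SEQ":
        outcomes = seq_outcomes(visits)
        perf = seq_performance(outcomes)
        lv = learning_visit(outcomes)
        sp_series = perf.sequence_performance
        valid = np.isfinite(sp_series)
        slv = learning_visit(sp_series[valid], positions=np.flatnonzero(valid).astype(float))
        tl = transition_learning(visits)
        return {
            "visit_performance": perf.final_visit_performance,
            "sequence_performance": perf.final_sequence_performance,
            "learning_visit": float(lv) if lv is not None else float("nan"),
            "sequence_learning_visit": float(slv) if slv is not None else float("nan"),
            "transition_learning_spread": (
                float(tl.spread) if tl.spread is not None else float("nan")
            ),
        }
    raise ValidationError(f"unknown task {visits.task!r}")
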