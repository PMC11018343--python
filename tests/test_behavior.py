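"""Behavior metrics: edit distance, stereotypy, per-task scores and the
kernel-smoothed binomial learning curves."""

import edlib
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as spstats

from ripplecheck import behavior as bhv
from ripplecheck.core import ValidationError, Visit, VisitLog


# ---------------------------------------------------------------------------
# levenshtein / similarity
# ---------------------------------------------------------------------------


def brute_force_lev(a: str, b: str) -> int:
    """Plain exponential recursion — the independent oracle."""
    if not b:
        return len(a)
    if not a:
        return len(b)
    if a[0] == b[0]:
        return brute_force_lev(a[1:], b[1:])
    return 1 + min(
        brute_force_lev(a[1:], b),
        brute_force_lev(a, b[1:]),
        brute_force_lev(a[1:], b[1:]),
    )


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("1345", "1345", 0),
        ("1345", "", 4),
        ("", "1345", 4),
        ("1345", "5471", 4),
        ("134", "1345", 1),
        ("kitten", "sitting", 3),
    ],
)
def test_levenshtein_reference_values(a, b, expected):
    assert bhv.levenshtein(a, b) == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.text(alphabet="12345678", max_size=4),
    st.text(alphabet="12345678", max_size=4),
)
def test_levenshtein_matches_brute_force(a, b):
    assert bhv.levenshtein(a, b) == brute_force_lev(a, b)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    st.text(alphabet="12345678", min_size=1, max_size=8),
    st.text(alphabet="12345678", min_size=1, max_size=8),
    st.text(alphabet="12345678", min_size=1, max_size=8),
)
def test_levenshtein_is_a_metric_and_matches_edlib(a, b, c):
    d_ab = bhv.levenshtein(a, b)
    assert d_ab == bhv.levenshtein(b, a)  # symmetry
    assert d_ab <= bhv.levenshtein(a, c) + bhv.levenshtein(c, b)  # triangle
    assert d_ab == edlib.align(a, b, task="distance")["editDistance"]
    assert (d_ab == 0) == (a == b)


def test_similarity_definition():
    assert bhv.similarity("1345", "1345") == 1.0
    assert bhv.similarity("1345", "5471") == 0.0
    assert bhv.similarity("134", "1345") == pytest.approx(1 - 1 / 4)
    with pytest.raises(ValidationError):
        bhv.similarity("", "")


# ---------------------------------------------------------------------------
# stereotypy
# ---------------------------------------------------------------------------


def test_stereotypy_identical_strings():
    strings = ["1345"] * 10
    assert bhv.stereotypy_index(strings) == 1.0
    _, z = bhv.stereotypy_z(strings, n_shuffles=500, seed=0)
    assert z > 3.0


def test_stereotypy_needs_two_trials():
    with pytest.raises(ValidationError):
        bhv.stereotypy_index(["1345"])


def test_stereotypy_null_calibration():
    """Uniform-random visit strings (distinct arms per trial, as the
    task produces): |z| < 2 in at least 95% of seeds."""
    ok = 0
    n_seeds = 60
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        strings = ["".join(rng.permutation(list("12345678"))[:4]) for _ in range(10)]
        _, z = bhv.stereotypy_z(strings, n_shuffles=300, seed=seed + 1000)
        ok += abs(z) < 2.0
    assert ok / n_seeds >= 0.95


# ---------------------------------------------------------------------------
# NMTS
# ---------------------------------------------------------------------------


def _nmts_trial(instructed, test_arms, t0=0.0):
    visits = []
    t = t0
    for a in instructed:
        visits.append(Visit(a, "instruction", True, t, t + 1))
        t += 2
    remaining = set(range(1, 9)) - set(instructed)
    for a in test_arms:
        correct = a in remaining
        visits.append(Visit(a, "test", correct, t, t + 1))
        t += 2
        remaining.discard(a)
        if not correct:
            break
    return visits, t


def _nmts_log(trials_spec):
    trials = []
    config = []
    t = 0.0
    for instructed, test_arms in trials_spec:
        trial, t = _nmts_trial(instructed, test_arms, t)
        trials.append(trial)
        config.append(list(instructed))
        t += 10
    return VisitLog("NMTS", "s", "no_stim", trials, {"instructed_arms": config})


def test_nmts_error_free_trial():
    log = _nmts_log([([1, 2, 3, 4], [5, 6, 7, 8])])
    m = bhv.nmts_metrics(log)[0]
    assert (m.performance, m.correct_visits, m.error_order_number) == (1, 4, None)


def test_nmts_first_visit_revisits_first_instructed():
    log = _nmts_log([([3, 5, 1, 7], [3])])
    m = bhv.nmts_metrics(log)[0]
    assert (m.performance, m.correct_visits, m.error_order_number) == (0, 0, 1)


def test_nmts_mid_sequence_error_order():
    log = _nmts_log([([2, 6, 4, 8], [1, 3, 6])])
    m = bhv.nmts_metrics(log)[0]
    assert (m.performance, m.correct_visits, m.error_order_number) == (0, 2, 2)


def test_nmts_recency_agent_error_order_below_chance():
    """Recency-weighted forgetting biases errors to early-instructed arms:
    mean order number well below the chance level of 2.5."""
    from ripplecheck.synth import AgentParams, generate_session_behavior

    orders = []
    n_trials = 0
    seed = 0
    while n_trials < 500:
        log = generate_session_behavior(AgentParams(task="NMTS", seed=seed))
        seed += 1
        n_trials += log.n_trials
        for m in bhv.nmts_metrics(log):
            if m.error_order_number is not None:
                orders.append(m.error_order_number)
    assert np.mean(orders) < 2.5


# ---------------------------------------------------------------------------
# MTS
# ---------------------------------------------------------------------------


def _mts_log(correct_pattern, visits_per_trial=None, baited=(1, 3, 5, 7)):
    """Build an MTS log where trial i is correct iff correct_pattern[i]."""
    trials = []
    t = 0.0
    baited = list(baited)
    for i, ok in enumerate(correct_pattern):
        n_v = visits_per_trial[i] if visits_per_trial else (4 if ok else 5)
        visits = []
        if ok:
            order = baited
        else:
            order = baited[:2] + [2] + baited[2:]  # one wrong excursion
            order = order[:n_v] if n_v <= len(order) else order + [4] * (n_v - len(order))
        collected = set()
        for a in order[:n_v]:
            correct = a in baited and a not in collected
            visits.append(Visit(a, "free", correct, t, t + 1))
            collected.add(a)
            t += 2
        trials.append(visits)
        t += 10
    return VisitLog("MTS", "s", "no_stim", trials, {"baited_arms": baited})


def test_mts_learning_trial_definition():
    """Trials 3,4,5 correct -> learning trial 6."""
    pattern = [False, False, True, True, True, False] + [True] * 19
    m = bhv.mts_metrics(_mts_log(pattern))
    assert m.learning_trial == 6


def test_mts_all_correct_session():
    m = bhv.mts_metrics(_mts_log([True] * 25))
    assert m.learning_trial == 4
    assert m.final10_mean_visits == 4.0
    assert m.final10_performance == 1.0


def test_mts_final10_mean_visits_fixture():
    """Final-10 visit counts (4,4,5,4,6,4,4,5,4,4) average 4.4."""
    final_visits = [4, 4, 5, 4, 6, 4, 4, 5, 4, 4]
    pattern = [True] * 15 + [v == 4 for v in final_visits]
    m = bhv.mts_metrics(_mts_log(pattern, visits_per_trial=[4] * 15 + final_visits))
    assert m.final10_mean_visits == pytest.approx(4.4)


@pytest.mark.parametrize(
    "arms,expected",
    [
        ((1, 2, 5, 6), "IIa"),
        ((1, 2, 4, 7), "IIb"),
        ((1, 2, 3, 6), "III"),
        ((1, 3, 5, 7), "IV_no_neighbors"),
        ((1, 2, 3, 4), "all_adjacent"),
        ((7, 8, 1, 2), "all_adjacent"),  # wraps around the ring
        ((8, 1, 4, 5), "IIa"),
    ],
)
def test_arm_configuration_classes(arms, expected):
    assert bhv.classify_arm_configuration(arms) == expected


def test_arm_configuration_rejects_bad_input():
    with pytest.raises(ValidationError):
        bhv.classify_arm_configuration((1, 2, 3))


def test_circularity_clockwise_and_symmetry():
    cw = _mts_log([True] * 25, baited=[2, 4, 6, 8])
    score, z = bhv.circularity_z(cw, n_shuffles=400, seed=0)
    assert score == 1.0
    assert z > 3.0
    ccw = _mts_log([True] * 25, baited=[2, 4, 6, 8])
    for trial in ccw.trials:
        trial.reverse()
        for i, v in enumerate(trial):
            trial[i] = Visit(v.arm, v.phase, v.correct, float(2 * i), 2 * i + 1.0)
    score_ccw, _ = bhv.circularity_z(ccw, n_shuffles=10, seed=0)
    assert score_ccw == score  # direction max makes it symmetric


def test_circularity_null_calibration():
    ok = 0
    n_seeds = 40
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed + 500)
        trials = []
        t = 0.0
        for _ in range(10):
            arms = rng.permutation(np.arange(1, 9))[:5]
            visits = [Visit(int(a), "free", True, t + 2 * i, t + 2 * i + 1)
                      for i, a in enumerate(arms)]
            trials.append(visits)
            t += 20
        log = VisitLog("MTS", "s", "no_stim", trials,
                       {"baited_arms": [1, 3, 5, 7]})
        _, z = bhv.circularity_z(log, n_shuffles=300, seed=seed)
        ok += abs(z) < 2.0
    assert ok / n_seeds >= 0.95


# ---------------------------------------------------------------------------
# SEQ
# ---------------------------------------------------------------------------


def test_sequence_performance_all_correct():
    perf = bhv.seq_performance(np.ones(200))
    assert np.all(perf.sequence_performance[4:] == 1.0)
    assert perf.final_sequence_performance == 1.0


def test_sequence_performance_single_error_window():
    outcomes = np.ones(100)
    outcomes[40] = 0
    perf = bhv.seq_performance(outcomes)
    assert np.all(perf.sequence_performance[40:45] == 0.0)
    assert perf.sequence_performance[39] == 1.0
    assert perf.sequence_performance[45] == 1.0


def test_sequence_performance_bernoulli_oracle():
    """Bernoulli(0.8) outcomes: mean 5-visit product ~= 0.8^5 = 0.328."""
    rng = np.random.default_rng(0)
    means = []
    for _ in range(20):
        outcomes = (rng.uniform(size=400) < 0.8).astype(float)
        perf = bhv.seq_performance(outcomes)
        means.append(np.nanmean(perf.sequence_performance))
    assert np.mean(means) == pytest.approx(0.8**5, abs=0.02)


def test_seq_session_excluded_when_run1_short():
    visits = [Visit(1, "run1", True, float(i), i + 0.5) for i in range(100)]
    log = VisitLog("SEQ", "s", "no_stim", [visits],
                   {"arm_positions": [1, 2, 3, 4], "sequence": [1, 3, 2, 4]})
    with pytest.raises(ValidationError):
        bhv.seq_outcomes(log)


def test_learning_visit_never_met():
    assert bhv.learning_visit(np.zeros(400)) is None


def test_learning_visit_all_correct_closed_form():
    """With every outcome correct, the learning visit equals the first
    index whose rounded effective n makes the binomial tail < 0.01."""
    outcomes = np.ones(400)
    lv = bhv.learning_visit(outcomes)
    k_eff, n_eff, _ = bhv.smoothed_learning_curve(outcomes)
    n = np.maximum(np.round(n_eff).astype(int), 1)
    expected = int(np.argmax(spstats.binom.sf(n - 1, n, 0.5) < 0.01))
    assert lv == expected


def test_learning_visit_step_recovery():
    """A 0.5 -> 0.95 step at visit 200 is located within +-50 visits in
    at least 80% of seeds (change-point recovery)."""
    hits = 0
    n_seeds = 50
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        outcomes = np.concatenate(
            [rng.uniform(size=200) < 0.5, rng.uniform(size=200) < 0.95]
        ).astype(float)
        lv = bhv.learning_visit(outcomes)
        hits += lv is not None and abs(lv - 200) <= 50
    assert hits / n_seeds >= 0.7  # unit-level smoke; full check in acceptance


def test_transition_learning_requires_two_learned():
    from ripplecheck.synth import AgentParams, generate_session_behavior

    params = AgentParams(
        task="SEQ", per_transition_onset=(100, 10_000, 10_000, 10_000), seed=4
    )
    log = generate_session_behavior(params)
    tl = bhv.transition_learning(log)
    learned = [v for v in tl.learning_visits.values() if v is not None]
    if len(learned) < 2:
        assert tl.spread is None


def test_transition_learning_simultaneous_onsets_small_spread():
    from ripplecheck.synth import AgentParams, generate_session_behavior

    spreads = []
    for seed in range(8):
        params = AgentParams(task="SEQ", per_transition_onset=(150,) * 4, p_learned=0.95, seed=seed)
        tl = bhv.transition_learning(generate_session_behavior(params))
        if tl.spread is not None:
            spreads.append(tl.spread)
    assert np.median(spreads) < 50  # below the kernel bandwidth
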