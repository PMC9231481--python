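"""Scoring tests: hand-counted examples, brute-force recounts, invariances."""

import math

import numpy as np
import pytest

from cogbattery import scoring
from cogbattery.cohort import SessionRecord

import oracles


def _enum_session(n_correct=17, n_total=20, condition="set5"):
    trials = [
        {"trial_index": i, "condition": condition, "correct": i < n_correct, "response": 5}
        for i in range(n_total)
    ]
    return SessionRecord("p0", 1, "enumeration", trials)


def test_enumeration_accuracy_direct_count():
    scores = scoring.score_conditions(_enum_session())
    assert len(scores) == 1
    assert scores[0].accuracy == pytest.approx(0.85)
    assert (scores[0].k, scores[0].n) == (17, 20)


def test_mot_partial_credit_hand_count():
    trials = [
        {"trial_index": i, "condition": "speed4", "n_correct": c, "n_targets": 5,
         "correct": c == 5}
        for i, c in enumerate([5, 4, 3])
    ]
    sess = SessionRecord("p0", 1, "mot", trials)
    (score,) = scoring.score_conditions(sess)
    assert (score.k, score.n) == (12, 15)
    assert score.accuracy == pytest.approx(0.8)


def test_lib_gating_hand_count():
    """20 trials, 2 foveal errors drop out, 9 peripheral correct among 18."""
    trials = []
    for i in range(20):
        foveal = i >= 2
        trials.append(
            {
                "trial_index": i,
                "condition": "near",
                "foveal_correct": foveal,
                "peripheral_correct": (i < 11) if foveal else None,
                "correct": foveal and i < 11,
            }
        )
    (score,) = scoring.score_conditions(SessionRecord("p0", 1, "lib", trials))
    assert (score.k, score.n) == (9, 18)
    assert score.accuracy == pytest.approx(0.5)


def test_lib_peripheral_n_never_exceeds_foveal_correct(small_sessions):
    for sess in small_sessions:
        if sess.task != "lib":
            continue
        n_foveal = sum(1 for t in sess.trials if t["foveal_correct"])
        assert sum(s.n for s in scoring.score_conditions(sess)) <= n_foveal


def test_gonogo_hit_and_false_alarm_rates():
    trials = []
    for i in range(18):
        trials.append({"trial_index": i, "condition": "go", "is_go": True,
                       "responded": i < 16, "correct": i < 16, "rt_ms": 400.0})
    for i in range(18):
        trials.append({"trial_index": 18 + i, "condition": "nogo", "is_go": False,
                       "responded": i < 1, "correct": i >= 1, "rt_ms": None})
    s = scoring.score_signal(SessionRecord("p0", 1, "gonogo", trials))
    assert s.hr == pytest.approx(16 / 18)
    assert s.far == pytest.approx(1 / 18)


def test_memorability_perfect_responder():
    trials = []
    for i in range(10):
        is_rep = i % 2 == 1
        trials.append(
            {"trial_index": i, "condition": "bedroom", "is_repeat": is_rep,
             "distance_class": "short" if is_rep else None,
             "responded": is_rep, "correct": True, "rt_ms": 800.0 if is_rep else None}
        )
    s = scoring.score_signal(SessionRecord("p0", 1, "memorability", trials))
    assert s.hr == 1.0 and s.far == 0.0


def test_memorability_long_distance_hr_matches_filter_oracle(small_sessions):
    for sess in small_sessions:
        if sess.task != "memorability":
            continue
        split = scoring.score_signal(sess, split_memorability=True)
        hits, n = oracles.recount_hr_by_distance(sess, "long")
        assert n == 16  # 8 long targets x 2 blocks
        assert split["hr_long"].hr == pytest.approx(hits / n)


def test_mean_rt_over_correct_trials_only():
    trials = [
        {"trial_index": 0, "condition": "go", "correct": True, "rt_ms": 500.0},
        {"trial_index": 1, "condition": "go", "correct": True, "rt_ms": 700.0},
        {"trial_index": 2, "condition": "go", "correct": False, "rt_ms": 100.0},
    ]
    rt = scoring.score_mean_rt(SessionRecord("p0", 1, "gonogo", trials))
    assert rt == {"go": pytest.approx(600.0)}


def test_mean_rt_absent_when_no_correct_trials():
    trials = [{"trial_index": 0, "condition": "go", "correct": False, "rt_ms": 300.0}]
    assert scoring.score_mean_rt(SessionRecord("p0", 1, "gonogo", trials)) == {}


def test_mean_rt_of_lognormal_sample_matches_closed_form():
    rng = np.random.default_rng(0)
    mu, sigma = math.log(600.0), 0.1
    trials = [
        {"trial_index": i, "condition": "go", "correct": True,
         "rt_ms": float(rng.lognormal(mu, sigma))}
        for i in range(10_000)
    ]
    rt = scoring.score_mean_rt(SessionRecord("p0", 1, "gonogo", trials))["go"]
    expected = 600.0 * math.exp(sigma**2 / 2.0)
    assert rt == pytest.approx(expected, rel=0.01)


def test_switch_cost_hand_values():
    trials = []
    for i, (sw, rt) in enumerate([(True, 900.0), (True, 900.0), (False, 700.0), (False, 700.0)]):
        trials.append({"trial_index": i, "condition": "odd_even", "task_type": "odd_even",
                       "is_switch": sw, "is_practice": False, "correct": True, "rt_ms": rt})
    costs = scoring.score_switch_cost(SessionRecord("p0", 1, "switch", trials))
    by_type = {c.task_type: c for c in costs}
    assert by_type["odd_even"].cost == pytest.approx(200.0)
    assert by_type["high_low"].flagged and by_type["high_low"].cost is None


def test_switch_cost_parameter_recovery():
    """A planted +150 ms switch shift is recovered within +-25 ms from 600
    main trials (costs pooled over the two task types)."""
    import cogbattery.schedules as sch
    from cogbattery import cohort

    profile = cohort.ParticipantProfile(
        participant_id="p0", age=30.0,
        ability={f: 0.0 for f in cohort.FAMILIES},
        speed_mu=math.log(450.0), speed_sigma=0.25, switch_cost_ms=150.0,
    )
    schedule = sch.generate_switch_session(n_per_task=300, n_practice=0, seed=21)
    sess = cohort.simulate_session(profile, schedule, day=1, seed=22)
    costs = [c.cost for c in scoring.score_switch_cost(sess)]
    assert np.mean(costs) == pytest.approx(150.0, abs=25.0)


def test_all_metrics_match_bruteforce_recount(small_sessions):
    """Every scored metric equals an independent recount from the raw
    session records alone."""
    for sess in small_sessions:
        if sess.task in scoring.CONDITION_TASKS:
            expected = oracles.recount_conditions(sess)
            got = {s.condition: (s.k, s.n) for s in scoring.score_conditions(sess)}
            assert got == expected
        else:
            if sess.task in scoring.SIGNAL_TASKS:
                hr, far = oracles.recount_signal(sess)
                s = scoring.score_signal(sess)
                assert s.hr == pytest.approx(hr) and s.far == pytest.approx(far)
            if sess.task == "switch":
                expected = oracles.recount_switch_cost(sess)
                got = {c.task_type: c.cost for c in scoring.score_switch_cost(sess)
                       if c.cost is not None}
                assert got.keys() == expected.keys()
                for k in got:
                    assert got[k] == pytest.approx(expected[k])
            assert scoring.score_mean_rt(sess) == pytest.approx(
                oracles.recount_mean_rt(sess)
            )


def test_accuracy_invariant_to_trial_order(small_sessions):
    rng = np.random.default_rng(1)
    for sess in small_sessions[:20]:
        if sess.task not in scoring.CONDITION_TASKS:
            continue
        shuffled = SessionRecord(
            sess.participant_id, sess.day, sess.task,
            [sess.trials[i] for i in rng.permutation(len(sess.trials))],
        )
        a = {s.condition: s.accuracy for s in scoring.score_conditions(sess)}
        b = {s.condition: s.accuracy for s in scoring.score_conditions(shuffled)}
        assert a == b


def test_empty_condition_flagged():
    sess = SessionRecord("p0", 1, "gonogo", [
        {"trial_index": 0, "condition": "go", "is_go": True, "responded": True,
         "correct": True, "rt_ms": 400.0}
    ])
    s = scoring.score_signal(sess)
    assert s.flagged and math.isnan(s.far)


def test_score_table_shape(small_scores):
    # per participant-day: 5 enum + 3 mot + 2 lib + 5 corsi + 3 gng + 3 mem + 2 switch
    assert set(small_scores.metric) == {"accuracy", "hr", "far", "rt", "switch_cost"}
    per_obs = small_scores.groupby(["participant_id", "day"]).size()
    assert (per_obs == 23).all()
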