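"""Per-task performance metrics computed from session records.

Metric definitions:

* accuracy per stimulus condition for enumeration, load-induced blindness
  (peripheral trials gated on a correct foveal response), multiple-object
  tracking (per-target partial credit: k correct targets over 5 x trials)
  and the spatial span task;
* hit rate / false-alarm rate for go/no-go and memorability (HR over
  second presentations, FAR over first presentations; HR optionally split
  by short vs long repeat distance);
* mean reaction time over correct trials only;
* switching cost = mean correct-trial RT on switch trials minus on
  non-switch trials, per task type, practice trials excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .cohort import SessionRecord

CONDITION_TASKS = ("enumeration", "lib", "mot", "corsi")
SIGNAL_TASKS = ("gonogo", "memorability")


@dataclass
class ConditionScore:
    task: str
    condition: str
    k: int
    n: int
    mean_rt_correct: float | None = None
    flagged: bool = False

    @property
    def accuracy(self) -> float:
        return self.k / self.n if self.n > 0 else math.nan


@dataclass
class SignalScores:
    task: str
    hr: float
    far: float
    n_signal: int
    n_noise: int
    flagged: bool = False


@dataclass
class SwitchCost:
    task_type: str
    rt_switch: float | None
    rt_nonswitch: float | None
    flagged: bool = False

    @property
    def cost(self) -> float | None:
        if self.rt_switch is None or self.rt_nonswitch is None:
            return None
        return self.rt_switch - self.rt_nonswitch


def _scored_trials(session: SessionRecord) -> list[dict]:
    """Trials that enter scoring: practice excluded."""
    return [t for t in session.trials if not t.get("is_practice", False)]


def score_conditions(session: SessionRecord) -> list[ConditionScore]:
    """One ConditionScore per stimulus condition of an accuracy task."""
    if session.task not in CONDITION_TASKS:
        raise ValueError(f"score_conditions expects one of {CONDITION_TASKS}, got {session.task!r}")
    by_cond: dict[str, list[dict]] = {}
    for t in _scored_trials(session):
        by_cond.setdefault(t["condition"], []).append(t)

    scores = []
    for cond in sorted(by_cond):
        trials = by_cond[cond]
        if session.task == "mot":
            k = sum(t["n_correct"] for t in trials)
            n = sum(t["n_targets"] for t in trials)
        elif session.task == "lib":
            # trials with a wrong foveal response carry no peripheral record
            recorded = [t for t in trials if t.get("peripheral_correct") is not None]
            k = sum(1 for t in recorded if t["peripheral_correct"])
            n = len(recorded)
        else:
            k = sum(1 for t in trials if t["correct"])
            n = len(trials)
        scores.append(
            ConditionScore(task=session.task, condition=cond, k=int(k), n=int(n), flagged=n == 0)
        )
    return scores


def score_signal(session: SessionRecord, split_memorability: bool = False):
    """Hit and false-alarm rates for the signal-detection style tasks.

    For memorability with ``split_memorability=True`` returns a dict with
    hit rates computed separately over the short- and long-distance repeats
    (keys ``hr_short``, ``hr_long``) alongside the overall rates.
    """
    if session.task not in SIGNAL_TASKS:
        raise ValueError(f"score_signal expects one of {SIGNAL_TASKS}, got {session.task!r}")
    trials = _scored_trials(session)
    if session.task == "gonogo":
        signal = [t for t in trials if t["is_go"]]
        noise = [t for t in trials if not t["is_go"]]
        hits = sum(1 for t in signal if t["responded"])
        fas = sum(1 for t in noise if t["responded"])
    else:
        signal = [t for t in trials if t["is_repeat"]]
        noise = [t for t in trials if not t["is_repeat"]]
        hits = sum(1 for t in signal if t["responded"])
        fas = sum(1 for t in noise if t["responded"])
    flagged = not signal or not noise
    scores = SignalScores(
        task=session.task,
        hr=hits / len(signal) if signal else math.nan,
        far=fas / len(noise) if noise else math.nan,
        n_signal=len(signal),
        n_noise=len(noise),
        flagged=flagged,
    )
    if session.task == "memorability" and split_memorability:
        out = {"overall": scores}
        for cls in ("short", "long"):
            sub = [t for t in signal if t["distance_class"] == cls]
            k = sum(1 for t in sub if t["responded"])
            out[f"hr_{cls}"] = SignalScores(
                task="memorability",
                hr=k / len(sub) if sub else math.nan,
                far=scores.far,
                n_signal=len(sub),
                n_noise=len(noise),
                flagged=not sub,
            )
        return out
    return scores


def score_mean_rt(session: SessionRecord) -> dict:
    """Mean RT (ms) over correct trials, per condition; conditions with no
    correct keyed trial are absent from the result."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for t in _scored_trials(session):
        if t.get("correct") and t.get("rt_ms") is not None:
            cond = t["condition"]
            sums[cond] = sums.get(cond, 0.0) + t["rt_ms"]
            counts[cond] = counts.get(cond, 0) + 1
    return {cond: sums[cond] / counts[cond] for cond in sums}


def correct_rts(session: SessionRecord, condition: str | None = None) -> list[float]:
    """Raw correct-trial RTs, optionally restricted to one condition."""
    return [
        t["rt_ms"]
        for t in _scored_trials(session)
        if t.get("correct")
        and t.get("rt_ms") is not None
        and (condition is None or t["condition"] == condition)
    ]


def score_switch_cost(session: SessionRecord) -> list[SwitchCost]:
    """Switching cost per task type on correct, non-practice trials.

    The first trial of the session (undefined switch status) is excluded.
    """
    if session.task != "switch":
        raise ValueError(f"score_switch_cost expects a switch session, got {session.task!r}")
    costs = []
    for task_type in ("odd_even", "high_low"):
        rts = {True: [], False: []}
        for t in _scored_trials(session):
            if (
                t["task_type"] == task_type
                and t["is_switch"] is not None
                and t["correct"]
                and t.get("rt_ms") is not None
            ):
                rts[t["is_switch"]].append(t["rt_ms"])
        rt_sw = sum(rts[True]) / len(rts[True]) if rts[True] else None
        rt_ns = sum(rts[False]) / len(rts[False]) if rts[False] else None
        costs.append(
            SwitchCost(
                task_type=task_type,
                rt_switch=rt_sw,
                rt_nonswitch=rt_ns,
                flagged=rt_sw is None or rt_ns is None,
            )
        )
    return costs


# ---------------------------------------------------------------------------
# Task-level scalars and the tidy score table
# ---------------------------------------------------------------------------


def task_scalar_accuracy(session: SessionRecord) -> float:
    """Single accuracy number per task, used for cross-day correlation and
    Bland-Altman: unweighted mean of condition accuracies for the
    condition-structured tasks; overall proportion correct (signal and
    noise trials pooled) for go/no-go and memorability; proportion correct
    on main-phase trials for task switching."""
    if session.task in CONDITION_TASKS:
        scores = [s.accuracy for s in score_conditions(session) if s.n > 0]
        return sum(scores) / len(scores) if scores else math.nan
    trials = _scored_trials(session)
    if not trials:
        return math.nan
    return sum(1 for t in trials if t["correct"]) / len(trials)


def task_scalar_counts(session: SessionRecord) -> tuple[int, int]:
    """(k, n) pooled over the task, matching task_scalar_accuracy's pooling
    for the signal tasks; for condition tasks, pooled raw counts."""
    if session.task == "mot":
        trials = _scored_trials(session)
        return (
            sum(t["n_correct"] for t in trials),
            sum(t["n_targets"] for t in trials),
        )
    if session.task == "lib":
        trials = [
            t for t in _scored_trials(session) if t.get("peripheral_correct") is not None
        ]
        return sum(1 for t in trials if t["peripheral_correct"]), len(trials)
    trials = _scored_trials(session)
    return sum(1 for t in trials if t["correct"]), len(trials)


def score_table(sessions: list[SessionRecord]) -> pd.DataFrame:
    """Tidy metric table over many sessions.

    Columns: participant_id, day, task, condition, metric, value, k, n.
    Rate metrics carry their (k, n); RT metrics have k = n = NA.
    """
    rows = []

    def add(sess, condition, metric, value, k=None, n=None):
        rows.append(
            {
                "participant_id": sess.participant_id,
                "day": sess.day,
                "task": sess.task,
                "condition": condition,
                "metric": metric,
                "value": value,
                "k": k,
                "n": n,
            }
        )

    for sess in sessions:
        if sess.task in CONDITION_TASKS:
            for s in score_conditions(sess):
                add(sess, s.condition, "accuracy", s.accuracy, s.k, s.n)
        elif sess.task == "gonogo":
            s = score_signal(sess)
            add(sess, "go", "hr", s.hr, round(s.hr * s.n_signal), s.n_signal)
            add(sess, "nogo", "far", s.far, round(s.far * s.n_noise), s.n_noise)
            rts = correct_rts(sess, "go")
            if rts:
                add(sess, "go", "rt", sum(rts) / len(rts))
        elif sess.task == "memorability":
            split = score_signal(sess, split_memorability=True)
            for cls in ("short", "long"):
                s = split[f"hr_{cls}"]
                add(sess, cls, "hr", s.hr, round(s.hr * s.n_signal), s.n_signal)
            s = split["overall"]
            add(sess, "first", "far", s.far, round(s.far * s.n_noise), s.n_noise)
        elif sess.task == "switch":
            for c in score_switch_cost(sess):
                if c.cost is not None:
                    add(sess, c.task_type, "switch_cost", c.cost)
        else:
            raise ValueError(f"unknown task {sess.task!r}")
    return pd.DataFrame(
        rows, columns=["participant_id", "day", "task", "condition", "metric", "value", "k", "n"]
    )
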