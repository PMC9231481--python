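"""Cross-day test-retest analyses.

Three complementary views of two-day stability:

* Pearson correlation of task-level scalar accuracies between days;
* Bland-Altman agreement on probit-transformed task accuracies
  (per-participant difference day 2 - day 1 against the two-day mean,
  with limits of agreement at mean +/- 1.96 SD);
* posterior difference distributions per condition (positive = second-day
  improvement), counting how many conditions have a 95% HDI that contains
  the no-difference point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import bayes, scoring
from .bayes import DifferenceDistribution, PosteriorEstimate
from .cohort import DEFAULT_DIFFICULTY, DEFAULT_POPULATION, SessionRecord
from .latent import FEATURE_COLUMNS, probit

logger = logging.getLogger(__name__)


def testretest_r(day1_scores, day2_scores) -> float:
    """Pearson r between paired per-participant scalars from the two days.

    Returns nan (with a logged warning) when either day has zero variance.
    """
    x = np.asarray(day1_scores, dtype=float)
    y = np.asarray(day2_scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("day scores must be paired 1-d vectors")
    if x.size < 3:
        raise ValueError(f"need >= 3 participants, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite scores")
    if x.std() == 0.0 or y.std() == 0.0:
        logger.warning("zero variance on one day; correlation undefined")
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class BlandAltman:
    means: np.ndarray  # per participant, (d1 + d2) / 2
    diffs: np.ndarray  # per participant, d2 - d1 (positive = day 2 better)
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ages: np.ndarray | None = None


def bland_altman(day1, day2, ages=None) -> BlandAltman:
    """Bland-Altman agreement summary for paired per-participant values."""
    x = np.asarray(day1, dtype=float)
    y = np.asarray(day2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("day values must be paired 1-d vectors")
    if x.size < 2:
        raise ValueError("need >= 2 participants for a difference SD")
    diffs = y - x
    means = (x + y) / 2.0
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    return BlandAltman(
        means=means,
        diffs=diffs,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        ages=None if ages is None else np.asarray(ages, dtype=float),
    )


def count_stable(differences: list[DifferenceDistribution]) -> tuple[int, int]:
    """(number of conditions whose 95% HDI contains zero, total conditions)."""
    if not differences:
        raise ValueError("empty difference list")
    n_stable = sum(1 for d in differences if d.contains_zero)
    return n_stable, len(differences)


# ---------------------------------------------------------------------------
# The condition-level cross-day battery
# ---------------------------------------------------------------------------


def _sessions_by_key(sessions: list[SessionRecord]) -> dict:
    out: dict[tuple, SessionRecord] = {}
    for s in sessions:
        out[(s.participant_id, s.day, s.task)] = s
    return out


def participant_estimate(
    sess: SessionRecord, condition: str, metric: str, draws: int, seed: int
) -> PosteriorEstimate | None:
    """Per-participant posterior for one battery condition, or None when the
    session carries no usable data for it."""
    if metric in ("accuracy", "hr", "far"):
        if sess.task in scoring.CONDITION_TASKS:
            match = [s for s in scoring.score_conditions(sess) if s.condition == condition]
            if not match or match[0].n == 0:
                return None
            k, n = match[0].k, match[0].n
        elif sess.task == "gonogo":
            sig = scoring.score_signal(sess)
            if metric == "hr":
                k, n = round(sig.hr * sig.n_signal), sig.n_signal
            else:
                k, n = round(sig.far * sig.n_noise), sig.n_noise
            if n == 0:
                return None
        else:  # memorability
            split = scoring.score_signal(sess, split_memorability=True)
            if metric == "far":
                s = split["overall"]
                k, n = round(s.far * s.n_noise), s.n_noise
            else:
                s = split[f"hr_{condition}"]
                k, n = round(s.hr * s.n_signal), s.n_signal
            if n == 0:
                return None
        return bayes.posterior_accuracy(int(k), int(n), draws=draws, seed=seed)

    if metric == "rt":
        rts = scoring.correct_rts(sess, condition)
        if len(rts) < 2:
            return None
        return bayes.posterior_rt(rts, draws=draws, seed=seed)

    if metric == "switch_cost":
        sw, ns = [], []
        for t in sess.trials:
            if (
                not t.get("is_practice", False)
                and t["task_type"] == condition
                and t["is_switch"] is not None
                and t["correct"]
            ):
                (sw if t["is_switch"] else ns).append(t["rt_ms"])
        if len(sw) < 2 or len(ns) < 2:
            return None
        upper = 2.0 * bayes.DEFAULT_RT_PRIOR_UPPER  # switch-trial RTs include the cost
        e_sw = bayes.posterior_rt(sw, draws=draws, seed=seed, prior_upper=upper)
        e_ns = bayes.posterior_rt(ns, draws=draws, seed=seed + 1, prior_upper=upper)
        return PosteriorEstimate.from_draws(e_sw.draws - e_ns.draws, kind="rt")

    raise ValueError(f"unknown metric {metric!r}")


def crossday_battery(
    sessions: list[SessionRecord],
    conditions: list[tuple[str, str, str, str]] | None = None,
    draws: int = 2000,
    seed: int = 0,
) -> list[DifferenceDistribution]:
    """Group-level cross-day posterior differences for each battery condition.

    For every condition: per-participant posteriors on each day, averaged
    draw-wise across participants, then contrasted with the improvement-
    positive sign convention.  The default condition set is the 23
    latent-analysis variables; pass ``conditions`` to extend it.
    """
    conditions = conditions or FEATURE_COLUMNS
    lookup = _sessions_by_key(sessions)
    pids = sorted({s.participant_id for s in sessions})
    rng = np.random.default_rng(seed)

    diffs = []
    for name, task, condition, metric in conditions:
        per_day: dict[int, list[PosteriorEstimate]] = {1: [], 2: []}
        for pid in pids:
            for day in (1, 2):
                sess = lookup.get((pid, day, task))
                if sess is None:
                    continue
                est = participant_estimate(
                    sess, condition, metric, draws, int(rng.integers(2**31))
                )
                if est is not None:
                    per_day[day].append(est)
        if not per_day[1] or not per_day[2]:
            logger.warning("condition %s has no data on one day; skipped", name)
            continue
        g1 = bayes.group_average(per_day[1])
        g2 = bayes.group_average(per_day[2])
        diffs.append(bayes.crossday_difference(g1, g2, condition=name))
    return diffs


@dataclass
class ReliabilityReport:
    pearson_r: dict  # task -> r on scalar accuracies
    bland_altman: dict  # task -> BlandAltman on probit accuracies
    differences: list = field(default_factory=list)
    n_stable: int = 0
    n_conditions: int = 0


def reliability_report(
    sessions: list[SessionRecord],
    ages: dict | None = None,
    draws: int = 2000,
    seed: int = 0,
    conditions: list[tuple[str, str, str, str]] | None = None,
) -> ReliabilityReport:
    """Full two-day reliability summary for a scored cohort."""
    lookup = _sessions_by_key(sessions)
    tasks = sorted({s.task for s in sessions})
    pids = sorted({s.participant_id for s in sessions})

    pearson, ba = {}, {}
    for task in tasks:
        d1_raw, d2_raw, d1_probit, d2_probit, age_list = [], [], [], [], []
        for pid in pids:
            s1, s2 = lookup.get((pid, 1, task)), lookup.get((pid, 2, task))
            if s1 is None or s2 is None:
                continue
            a1, a2 = scoring.task_scalar_accuracy(s1), scoring.task_scalar_accuracy(s2)
            if not (np.isfinite(a1) and np.isfinite(a2)):
                continue
            d1_raw.append(a1)
            d2_raw.append(a2)
            _, n1 = scoring.task_scalar_counts(s1)
            _, n2 = scoring.task_scalar_counts(s2)
            d1_probit.append(probit(a1, max(n1, 1)))
            d2_probit.append(probit(a2, max(n2, 1)))
            age_list.append(None if ages is None else ages.get(pid))
        if len(d1_raw) >= 3:
            pearson[task] = testretest_r(d1_raw, d2_raw)
        if len(d1_probit) >= 2:
            ba[task] = bland_altman(
                d1_probit,
                d2_probit,
                ages=None if ages is None else [a for a in age_list],
            )

    differences = crossday_battery(sessions, conditions=conditions, draws=draws, seed=seed)
    n_stable, n_conditions = count_stable(differences) if differences else (0, 0)
    return ReliabilityReport(
        pearson_r=pearson,
        bland_altman=ba,
        differences=differences,
        n_stable=n_stable,
        n_conditions=n_conditions,
    )


# ---------------------------------------------------------------------------
# Null-cohort coverage study
# ---------------------------------------------------------------------------

#: Per-condition study design for the coverage simulation: trial counts per
#: participant-day at the battery's standard session sizes, and the latent
#: difficulty (logit units) drawn from the simulator's default table.
_COVERAGE_RATE_CONDITIONS = [
    *[(f"enum_acc_set{n}", 20, DEFAULT_DIFFICULTY["enumeration"][f"set{n}"]) for n in (5, 6, 7, 8, 9)],
    *[(f"mot_acc_speed{s}", 50, DEFAULT_DIFFICULTY["mot"][f"speed{s}"]) for s in (1, 4, 8)],
    ("lib_acc_near", 18, DEFAULT_DIFFICULTY["lib"]["near"]),
    ("lib_acc_far", 18, DEFAULT_DIFFICULTY["lib"]["far"]),
    *[(f"wm_acc_len{n}", 12, DEFAULT_DIFFICULTY["corsi"][f"len{n}"]) for n in (4, 5, 6, 7, 8)],
    ("mem_hr_short", 64, -0.62),  # -logit(0.65): median hit rate 0.65
    ("mem_hr_long", 16, -0.12),  # short-distance base plus the long penalty
    ("mem_far", 160, 1.73),  # median false-alarm rate ~0.15
    ("gng_hr", 18, DEFAULT_DIFFICULTY["gonogo"]["go"]),
    ("gng_far", 18, 2.0),  # median commission rate ~0.12
]

# (name, trials per cell, log-mean shift); switch costs are differences of
# two RT-mean posteriors
_COVERAGE_RT_CONDITIONS = [
    ("gng_rt", 16, None, DEFAULT_POPULATION["rt_task_shift"]["gonogo"]),
    ("switch_cost_odd_even", 14, 14, DEFAULT_POPULATION["rt_task_shift"]["switch"]),
    ("switch_cost_high_low", 14, 14, DEFAULT_POPULATION["rt_task_shift"]["switch"]),
]


def _hdi_contains_zero(diffs: np.ndarray, mass: float = 0.95) -> np.ndarray:
    """Vectorized 95% HDI zero-coverage over the last axis of (R, D) draws."""
    x = np.sort(diffs, axis=-1)
    n = x.shape[-1]
    m = max(1, int(math.ceil(mass * n)))
    if m >= n:
        lo, hi = x[..., 0], x[..., -1]
    else:
        widths = x[..., m:] - x[..., : n - m]
        i = np.argmin(widths, axis=-1)
        lo = np.take_along_axis(x, i[..., None], axis=-1)[..., 0]
        hi = np.take_along_axis(x, (i + m)[..., None], axis=-1)[..., 0]
    return (lo <= 0.0) & (hi >= 0.0)


def null_coverage_simulation(
    n_participants: int = 50,
    n_replicates: int = 200,
    draws: int = 2000,
    seed: int = 0,
    chunk: int = 25,
) -> dict:
    """Zero-coverage of cross-day HDIs under a null cohort (no day effect).

    Replicate cohorts are simulated at the battery's standard trial counts
    with identical day-1 and day-2 generating parameters; for each
    condition the group-level cross-day difference HDI is computed and the
    fraction containing zero is returned.  Counts are drawn at the
    binomial level (trial-wise Bernoulli responses and their per-condition
    success count are the same distribution), which keeps 200 replicates
    tractable.
    """
    rng = np.random.default_rng(seed)
    P, D = n_participants, draws
    results: dict[str, int] = {}
    total = 0
    covered = 0

    for name, n_trials, difficulty in _COVERAGE_RATE_CONDITIONS:
        hits = 0
        for start in range(0, n_replicates, chunk):
            r = min(chunk, n_replicates - start)
            ability = rng.normal(0.0, 1.0, size=(r, P))
            p = 1.0 / (1.0 + np.exp(-(ability - difficulty)))
            post = []
            for _day in (1, 2):
                k = rng.binomial(n_trials, p)  # (r, P)
                g = rng.beta(1 + k[..., None], 1 + n_trials - k[..., None], size=(r, P, D))
                post.append(g.mean(axis=1))  # group average, (r, D)
            hits += int(_hdi_contains_zero(post[1] - post[0]).sum())
        results[name] = hits
        covered += hits
        total += n_replicates

    for name, m1, m2, shift in _COVERAGE_RT_CONDITIONS:
        mu0 = DEFAULT_POPULATION["speed_log_mean"] + shift
        sig = DEFAULT_POPULATION["speed_sigma"]
        hits = 0
        for start in range(0, n_replicates, chunk):
            r = min(chunk, n_replicates - start)
            speed_mu = mu0 - DEFAULT_POPULATION["speed_log_slope"] * rng.normal(size=(r, P))
            cost = (
                DEFAULT_POPULATION["switch_cost_mean_ms"]
                - DEFAULT_POPULATION["switch_cost_sd_ms"] * rng.normal(size=(r, P))
                if m2 is not None
                else None
            )
            post = []
            for _day in (1, 2):
                rts = rng.lognormal(speed_mu[..., None], sig, size=(r, P, m1))
                if cost is not None:
                    rts = rts + cost[..., None]
                xbar = rts.mean(axis=-1)
                se = rts.std(axis=-1, ddof=1) / math.sqrt(m1)
                est = xbar[..., None] + se[..., None] * rng.normal(size=(r, P, D))
                if cost is not None:
                    rts2 = rng.lognormal(speed_mu[..., None], sig, size=(r, P, m2))
                    xbar2 = rts2.mean(axis=-1)
                    se2 = rts2.std(axis=-1, ddof=1) / math.sqrt(m2)
                    est = est - (xbar2[..., None] + se2[..., None] * rng.normal(size=(r, P, D)))
                post.append(est.mean(axis=1))
            hits += int(_hdi_contains_zero(post[0] - post[1]).sum())
        results[name] = hits
        covered += hits
        total += n_replicates

    return {
        "per_condition": results,
        "n_replicates": n_replicates,
        "n_conditions": len(results),
        "coverage": covered / total,
    }
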