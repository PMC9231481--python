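"""Synthetic participant cohorts and trial-by-trial response simulation.

The simulator exists so that every downstream stage (scoring, posterior
estimation, reliability, latent factors) is testable without human data.
Its response model is deliberately simple and fully parameterized:

* accuracy: P(correct) = logistic(ability - condition difficulty + day shift),
  with one latent ability per condition family and a difficulty table that
  is monotone in set size / speed / sequence length;
* reaction time on keyed tasks: lognormal(speed_mu + task shift, speed_sigma),
  with a per-participant additive cost on task-switch trials so the
  simulated switching cost is positive in expectation;
* memorability: hit probability = logistic(logit of the image's nominal hit
  rate + ability + day shift - a penalty for long repeat distances).

A cohort can carry a planted low-rank factor structure (ability vector =
loadings x latent traits + noise), which the latent-factor tests use for
parameter recovery.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from . import schedules as sch
from .errors import ConfigError

FAMILIES = (
    "enumeration",
    "mot",
    "lib",
    "corsi",
    "memorability",
    "gonogo",
    "switch",
    "speed",
)

#: Condition difficulties in logit units; larger = harder.  Chosen so a
#: median participant (ability 0) spans roughly the accuracy ranges seen in
#: adult norms for these paradigms, and strictly monotone within each task.
DEFAULT_DIFFICULTY = {
    "enumeration": {"set5": -2.2, "set6": -1.5, "set7": -0.9, "set8": -0.4, "set9": 0.0},
    "mot": {"speed1": -2.2, "speed4": -0.8, "speed8": 0.2},
    "lib": {"near": 0.2, "far": 0.6},
    "corsi": {"len4": -2.0, "len5": -1.2, "len6": -0.4, "len7": 0.4, "len8": 1.2},
    "gonogo": {"go": -2.4, "nogo": -2.0},  # nogo entry drives false alarms
    "switch": {"odd_even": -3.0, "high_low": -3.0},
}

DEFAULT_POPULATION = {
    "ability_mean": {f: 0.0 for f in FAMILIES},
    "ability_sd": {f: 1.0 for f in FAMILIES},
    "speed_log_mean": math.log(450.0),  # baseline keyed RT ~450 ms
    "speed_log_slope": 0.15,  # log-RT decrease per unit speed ability
    "speed_sigma": 0.25,  # within-participant lognormal dispersion
    "switch_cost_mean_ms": 150.0,
    "switch_cost_sd_ms": 50.0,
    "lib_foveal_p": 0.9,
    "memorability_long_penalty": 0.5,  # logits; makes HR_long < HR_short
    "memorability_fa_base": float(logit(0.15)),
    "memorability_fa_weight": 0.8,
    "rt_task_shift": {"gonogo": 0.0, "switch": 0.29, "memorability": 0.69},
    "day_effect": {1: 0.0, 2: 0.0},  # logit units, added to accuracy only
    "age_range": (21, 71),
}

DEFAULT_MOT_TRIALS_PER_SPEED = 10


@dataclass
class ParticipantProfile:
    """Latent parameters driving one simulated participant."""

    participant_id: str
    age: float
    ability: dict  # condition family -> logit-scale ability
    speed_mu: float  # log-ms baseline of keyed RT
    speed_sigma: float  # log-ms dispersion, > 0
    switch_cost_ms: float
    lib_foveal_p: float = 0.9
    day_effect: dict = field(default_factory=lambda: {1: 0.0, 2: 0.0})
    traits: np.ndarray | None = None  # planted latent traits, if any

    def __post_init__(self):
        if not self.speed_sigma > 0:
            raise ValueError("speed_sigma must be positive")
        for fam, a in self.ability.items():
            if not np.isfinite(a) and not np.isinf(a):
                raise ValueError(f"ability[{fam!r}] must be finite (or +/-inf override)")


@dataclass
class SessionRecord:
    """All trials of one participant-day-task, joined to simulated responses.

    ``trials`` is a list of flat dicts; the keys present depend on the task
    (see :mod:`cogbattery.battery_io` for the pinned serialization schema).
    """

    participant_id: str
    day: int
    task: str
    trials: list


def _merged_config(config: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_POPULATION)
    cfg["difficulty"] = copy.deepcopy(DEFAULT_DIFFICULTY)
    if config:
        for key, value in config.items():
            if key == "planted":
                cfg["planted"] = copy.deepcopy(value)
                continue
            if key not in cfg:
                raise ConfigError(f"unknown cohort config key {key!r}")
            if isinstance(cfg[key], dict) and isinstance(value, dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def _sample_traits(rng: np.random.Generator, n: int, k: int, dist: str) -> np.ndarray:
    """Unit-variance latent traits; non-Gaussian options keep ICA identifiable."""
    if dist == "uniform":
        return rng.uniform(-math.sqrt(3.0), math.sqrt(3.0), size=(n, k))
    if dist == "laplace":
        return rng.laplace(0.0, 1.0 / math.sqrt(2.0), size=(n, k))
    if dist == "normal":
        return rng.normal(0.0, 1.0, size=(n, k))
    raise ConfigError(f"unknown trait distribution {dist!r}")


def sample_cohort(
    n: int, config: dict | None = None, seed: int = 0
) -> list[ParticipantProfile]:
    """Draw ``n`` participant profiles from the configured population.

    With ``config["planted"] = {"k": ..., "loadings": {family: [..]}, ...}``
    the family abilities become loadings x latent traits + noise, enabling
    factor-recovery tests downstream.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = _merged_config(config)
    rng = np.random.default_rng(seed)
    planted = cfg.get("planted")

    traits = None
    if planted is not None:
        k = int(planted.get("k", 2))
        loadings = planted.get("loadings")
        if loadings is None or any(f not in loadings for f in FAMILIES):
            raise ConfigError("planted config must give a loading row per family")
        L = np.array([loadings[f] for f in FAMILIES], dtype=float)  # (families, k)
        if L.shape[1] != k:
            raise ConfigError(f"loading rows must have length k={k}")
        noise_sd = float(planted.get("noise_sd", 0.3))
        traits = _sample_traits(rng, n, k, planted.get("trait_dist", "uniform"))

    age_lo, age_hi = cfg["age_range"]
    profiles = []
    for i in range(n):
        if traits is not None:
            vec = L @ traits[i] + rng.normal(0.0, noise_sd, size=len(FAMILIES))
            ability = {f: float(cfg["ability_mean"][f] + v) for f, v in zip(FAMILIES, vec)}
        else:
            ability = {
                f: float(rng.normal(cfg["ability_mean"][f], cfg["ability_sd"][f]))
                for f in FAMILIES
            }
        a_speed = ability["speed"]
        profiles.append(
            ParticipantProfile(
                participant_id=f"p{i:03d}",
                age=float(rng.uniform(age_lo, age_hi)),
                ability=ability,
                speed_mu=cfg["speed_log_mean"] - cfg["speed_log_slope"] * a_speed,
                speed_sigma=cfg["speed_sigma"],
                switch_cost_ms=cfg["switch_cost_mean_ms"]
                - cfg["switch_cost_sd_ms"] * a_speed,
                lib_foveal_p=cfg["lib_foveal_p"],
                day_effect=dict(cfg["day_effect"]),
                traits=None if traits is None else traits[i].copy(),
            )
        )
    return profiles


def _p_correct(cfg: dict, profile: ParticipantProfile, family: str, condition: str, day: int) -> float:
    table = cfg["difficulty"].get(family)
    if table is None or condition not in table:
        raise ConfigError(f"no difficulty entry for {family}/{condition}")
    shift = profile.day_effect.get(day, 0.0)
    return float(expit(profile.ability[family] - table[condition] + shift))


def _rt_ms(rng: np.random.Generator, profile: ParticipantProfile, task_shift: float) -> float:
    return float(rng.lognormal(profile.speed_mu + task_shift, profile.speed_sigma))


def simulate_session(
    profile: ParticipantProfile,
    schedule: list,
    day: int,
    seed: int,
    config: dict | None = None,
) -> SessionRecord:
    """Simulate one participant-day response set for a task schedule.

    ``schedule`` is a list of trial objects from :mod:`cogbattery.schedules`
    (for memorability, a list of blocks); the task is inferred from the
    trial type.  Fixing (profile, schedule, day, seed) reproduces the
    identical record.
    """
    if day not in (1, 2):
        raise ValueError(f"day must be 1 or 2, got {day}")
    if not schedule:
        raise ValueError("empty schedule")
    cfg = _merged_config(config)
    rng = np.random.default_rng(seed)
    first = schedule[0]

    if isinstance(first, sch.MotTrial):
        return _simulate_mot(profile, schedule, day, rng, cfg)
    if isinstance(first, sch.EnumerationTrial):
        return _simulate_enumeration(profile, schedule, day, rng, cfg)
    if isinstance(first, sch.LibTrial):
        return _simulate_lib(profile, schedule, day, rng, cfg)
    if isinstance(first, sch.GoNoGoTrial):
        return _simulate_gonogo(profile, schedule, day, rng, cfg)
    if isinstance(first, sch.SwitchTrial):
        return _simulate_switch(profile, schedule, day, rng, cfg)
    if isinstance(first, sch.CorsiTrial):
        return _simulate_corsi(profile, schedule, day, rng, cfg)
    if isinstance(first, sch.MemorabilityBlock):
        return _simulate_memorability(profile, schedule, day, rng, cfg)
    raise ValueError(f"unrecognized schedule element {type(first).__name__}")


def _simulate_mot(profile, schedule, day, rng, cfg) -> SessionRecord:
    trials = []
    for idx, trial in enumerate(schedule):
        p = _p_correct(cfg, profile, "mot", trial.condition, day)
        n_targets = len(trial.target_indices)
        n_correct = int(rng.binomial(n_targets, p))
        trials.append(
            {
                "trial_index": idx,
                "condition": trial.condition,
                "n_correct": n_correct,
                "n_targets": n_targets,
                "correct": n_correct == n_targets,
            }
        )
    return SessionRecord(profile.participant_id, day, "mot", trials)


def _simulate_enumeration(profile, schedule, day, rng, cfg) -> SessionRecord:
    trials = []
    for idx, trial in enumerate(schedule):
        p = _p_correct(cfg, profile, "enumeration", trial.condition, day)
        correct = bool(rng.uniform() < p)
        reported = trial.n_circles if correct else trial.n_circles + int(rng.choice([-1, 1]))
        trials.append(
            {
                "trial_index": idx,
                "condition": trial.condition,
                "correct": correct,
                "response": int(reported),
            }
        )
    return SessionRecord(profile.participant_id, day, "enumeration", trials)


def _simulate_lib(profile, schedule, day, rng, cfg) -> SessionRecord:
    trials = []
    for idx, trial in enumerate(schedule):
        foveal = bool(rng.uniform() < profile.lib_foveal_p)
        if foveal:
            p = _p_correct(cfg, profile, "lib", trial.condition, day)
            peripheral = bool(rng.uniform() < p)
        else:
            peripheral = None  # response to the peripheral task not recorded
        trials.append(
            {
                "trial_index": idx,
                "condition": trial.condition,
                "foveal_correct": foveal,
                "peripheral_correct": peripheral,
                "correct": bool(peripheral) if peripheral is not None else False,
            }
        )
    return SessionRecord(profile.participant_id, day, "lib", trials)


def _simulate_gonogo(profile, schedule, day, rng, cfg) -> SessionRecord:
    shift = cfg["rt_task_shift"]["gonogo"]
    trials = []
    for idx, trial in enumerate(schedule):
        if trial.is_go:
            responded = bool(rng.uniform() < _p_correct(cfg, profile, "gonogo", "go", day))
            correct = responded
        else:
            # the nogo difficulty entry drives the commission (false alarm) rate
            fa_p = 1.0 - _p_correct(cfg, profile, "gonogo", "nogo", day)
            responded = bool(rng.uniform() < fa_p)
            correct = not responded
        rt = _rt_ms(rng, profile, shift) if responded else None
        trials.append(
            {
                "trial_index": idx,
                "condition": trial.condition,
                "is_go": trial.is_go,
                "responded": responded,
                "correct": correct,
                "rt_ms": rt,
            }
        )
    return SessionRecord(profile.participant_id, day, "gonogo", trials)


def _simulate_switch(profile, schedule, day, rng, cfg) -> SessionRecord:
    shift = cfg["rt_task_shift"]["switch"]
    trials = []
    for idx, trial in enumerate(schedule):
        p = _p_correct(cfg, profile, "switch", trial.task_type, day)
        correct = bool(rng.uniform() < p)
        rt = _rt_ms(rng, profile, shift)
        if trial.is_switch:
            rt += profile.switch_cost_ms
        trials.append(
            {
                "trial_index": idx,
                "condition": trial.task_type,
                "task_type": trial.task_type,
                "is_switch": trial.is_switch,
                "is_practice": trial.is_practice,
                "correct": correct,
                "rt_ms": float(rt),
            }
        )
    return SessionRecord(profile.participant_id, day, "switch", trials)


def _simulate_corsi(profile, schedule, day, rng, cfg) -> SessionRecord:
    trials = []
    for idx, trial in enumerate(schedule):
        p = _p_correct(cfg, profile, "corsi", trial.condition, day)
        trials.append(
            {
                "trial_index": idx,
                "condition": trial.condition,
                "length": trial.length,
                "correct": bool(rng.uniform() < p),  # all-or-nothing sequence recall
            }
        )
    return SessionRecord(profile.participant_id, day, "corsi", trials)


def _simulate_memorability(profile, schedule, day, rng, cfg) -> SessionRecord:
    shift = cfg["rt_task_shift"]["memorability"]
    a = profile.ability["memorability"]
    day_shift = profile.day_effect.get(day, 0.0)
    fa_p = float(expit(cfg["memorability_fa_base"] - cfg["memorability_fa_weight"] * a))
    trials = []
    idx = 0
    for block in schedule:
        seen: set[str] = set()
        for image_id in block.presentation_order:
            is_repeat = image_id in seen
            seen.add(image_id)
            if is_repeat:
                base = logit(block.hit_rates.get(image_id, 0.65))
                dist_class = block.distance_class(image_id)
                penalty = cfg["memorability_long_penalty"] if dist_class == "long" else 0.0
                hit_p = float(expit(base + a + day_shift - penalty))
                responded = bool(rng.uniform() < hit_p)
                correct = responded
            else:
                dist_class = None
                responded = bool(rng.uniform() < fa_p)
                correct = not responded
            trials.append(
                {
                    "trial_index": idx,
                    "condition": block.category,
                    "is_repeat": is_repeat,
                    "distance_class": block.distance_class(image_id) if is_repeat else None,
                    "responded": responded,
                    "correct": correct,
                    "rt_ms": _rt_ms(rng, profile, shift) if responded else None,
                }
            )
            idx += 1
    return SessionRecord(profile.participant_id, day, "memorability", trials)


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------


def generate_day_schedules(
    seed: int,
    catalog: list[sch.ImageRecord] | None = None,
    mot_trials_per_speed: int = DEFAULT_MOT_TRIALS_PER_SPEED,
) -> dict:
    """Generate one participant-day's worth of schedules for all seven tasks,
    at the battery's standard trial counts."""
    rng = np.random.default_rng(seed)

    def sub() -> int:
        return int(rng.integers(2**31))

    if catalog is None:
        catalog = sch.make_synthetic_catalog(seed=sub())
    mot = [
        sch.generate_mot_trial(speed, sub())
        for speed in sch.MOT_SPEEDS
        for _ in range(mot_trials_per_speed)
    ]
    enumeration = [
        sch.generate_enumeration_trial(n, sub())
        for n in sch.ENUM_SET_SIZES
        for _ in range(sch.ENUM_TRIALS_PER_CONDITION)
    ]
    lib = [
        sch.generate_lib_trial(ecc, sub())
        for ecc in sch.LIB_ECCENTRICITIES
        for _ in range(sch.LIB_TRIALS_PER_CONDITION)
    ]
    return {
        "mot": mot,
        "enumeration": enumeration,
        "lib": lib,
        "gonogo": sch.generate_gonogo_session(seed=sub()),
        "switch": sch.generate_switch_session(seed=sub()),
        "corsi": sch.generate_corsi_session(seed=sub()),
        "memorability": [
            sch.generate_memorability_block(catalog, cat, sub())
            for cat in sch.MEM_CATEGORIES
        ],
    }


def simulate_study(
    profiles: list[ParticipantProfile],
    seed: int = 0,
    config: dict | None = None,
    days: tuple[int, ...] = (1, 2),
    tasks: tuple[str, ...] = sch.TASKS,
) -> list[SessionRecord]:
    """Simulate the full two-day battery for a cohort.

    Each participant-day gets freshly randomized schedules (as in the real
    battery); all randomness derives from ``seed``.
    """
    rng = np.random.default_rng(seed)
    catalog = sch.make_synthetic_catalog(seed=int(rng.integers(2**31)))
    records: list[SessionRecord] = []
    for profile in profiles:
        for day in days:
            schedules = generate_day_schedules(
                int(rng.integers(2**31)), catalog=catalog
            )
            for task in tasks:
                records.append(
                    simulate_session(
                        profile,
                        schedules[task],
                        day,
                        int(rng.integers(2**31)),
                        config=config,
                    )
                )
    return records
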