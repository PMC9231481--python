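"""Independent structural validators for emitted schedules.

These inspect only the emitted schedule objects (or their JSON payloads),
never generator internals, so they double as oracles in the test suite.
Each ``validate_*`` function returns a list of violation strings; an empty
list means the schedule is structurally sound.  :func:`check` raises
:class:`~cogbattery.errors.ValidationError` on any violation.
"""

from __future__ import annotations

import numpy as np

from . import schedules as sch
from .errors import ValidationError


def validate_mot_trial(trial: sch.MotTrial, tol: float = 1e-6) -> list[str]:
    v: list[str] = []
    pos = np.asarray(trial.disc_positions, dtype=float)
    if pos.ndim != 3 or pos.shape[1] != sch.MOT_N_DISCS or pos.shape[2] != 2:
        v.append(f"disc_positions shape {pos.shape}, expected (frames, 10, 2)")
        return v
    if len(trial.target_indices) != sch.MOT_N_TARGETS:
        v.append(f"{len(trial.target_indices)} targets, expected 5")
    if len(set(trial.target_indices)) != len(trial.target_indices):
        v.append("duplicate target indices")
    if any(t < 0 or t >= sch.MOT_N_DISCS for t in trial.target_indices):
        v.append("target index out of range")
    half = trial.canvas / 2.0
    if np.any(np.abs(pos) > half + tol):
        v.append("disc position outside canvas bounds")
    # constant-speed check away from the walls: a frame-to-frame step must
    # have magnitude speed/frame_rate unless the disc touched a wall
    step = trial.speed / trial.frame_rate
    disp = np.linalg.norm(np.diff(pos, axis=0), axis=2)  # (frames-1, discs)
    margin = half - trial.disc_diameter / 2.0 - step
    near_wall = np.any(np.abs(pos) > margin, axis=2)  # (frames, discs)
    free = ~(near_wall[:-1] | near_wall[1:])
    if np.any(np.abs(disp[free] - step) > max(tol, 1e-9)):
        v.append("non-bounce frame displacement differs from speed/frame_rate")
    return v


def infer_mot_speed(trial: sch.MotTrial) -> float:
    """Recover the disc speed from a stored trajectory alone (energy check):
    median per-frame displacement x frame rate."""
    pos = np.asarray(trial.disc_positions, dtype=float)
    disp = np.linalg.norm(np.diff(pos, axis=0), axis=2)
    return float(np.median(disp) * trial.frame_rate)


def validate_enumeration_trial(trial: sch.EnumerationTrial) -> list[str]:
    v: list[str] = []
    centers = np.asarray(trial.circle_centers, dtype=float)
    if centers.shape != (trial.n_circles, 2):
        v.append(f"{centers.shape[0]} centers for n_circles={trial.n_circles}")
        return v
    r_region = trial.region_diameter / 2.0
    if np.any(np.hypot(centers[:, 0], centers[:, 1]) > r_region + 1e-9):
        v.append("circle center outside the presentation region")
    # brute-force O(n^2) overlap check
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.hypot(*(centers[i] - centers[j])) < trial.circle_diameter - 1e-9:
                v.append(f"circles {i} and {j} overlap")
    return v


def validate_lib_trial(trial: sch.LibTrial) -> list[str]:
    v: list[str] = []
    if sorted(trial.cross_lengths.values()) != sorted(sch.LIB_CROSS_LENGTHS):
        v.append(f"cross arm lengths {trial.cross_lengths} not {{0.5, 1.0}}")
    n_target = sum(1 for c in trial.contrasts if c == sch.LIB_TARGET_CONTRAST)
    n_other = sum(1 for c in trial.contrasts if c == sch.LIB_NONTARGET_CONTRAST)
    if n_target != 1 or n_other != 3:
        v.append(f"contrast pattern {trial.contrasts} not one 0.8 among 0.4s")
    if trial.contrasts[trial.target_quadrant] != sch.LIB_TARGET_CONTRAST:
        v.append("target_quadrant does not carry the enhanced contrast")
    ecc = np.hypot(trial.gabor_positions[:, 0], trial.gabor_positions[:, 1])
    if np.any(np.abs(ecc - trial.gabor_eccentricity) > 1e-9):
        v.append("gabor not at the stated eccentricity")
    return v


def validate_gonogo_trial(trial: sch.GoNoGoTrial) -> list[str]:
    v: list[str] = []
    stream = trial.digit_stream
    cue_positions = [i for i, d in enumerate(stream) if d == sch.GONOGO_CUE]
    if len(cue_positions) != 1:
        v.append(f"{len(cue_positions)} cue digits in stream, expected exactly 1")
        return v
    cue_at = cue_positions[0]
    if cue_at + 1 >= len(stream):
        v.append("cue is the last digit; no probe follows")
        return v
    if stream[cue_at + 1] != trial.probe_digit:
        v.append("stored probe_digit differs from the digit after the cue")
    if trial.is_go != (trial.probe_digit == sch.GONOGO_GO_PROBE):
        v.append("is_go flag inconsistent with probe digit")
    return v


def validate_switch_session(trials: list[sch.SwitchTrial]) -> list[str]:
    v: list[str] = []
    for i, t in enumerate(trials):
        if t.digit == 5 or t.digit not in sch.SWITCH_DIGITS:
            v.append(f"trial {i}: digit {t.digit} outside 1-4, 6-9")
        if t.correct_key != sch.switch_correct_key(t.cue, t.digit):
            v.append(f"trial {i}: correct_key violates the response rule")
        expected = None if i == 0 else t.cue != trials[i - 1].cue
        if t.is_switch != expected:
            v.append(f"trial {i}: is_switch {t.is_switch}, expected {expected}")
    return v


def validate_corsi_trial(trial: sch.CorsiTrial) -> list[str]:
    v: list[str] = []
    seq = trial.flash_sequence
    if len(seq) != trial.length:
        v.append(f"sequence length {len(seq)} != stated length {trial.length}")
    if len(set(seq)) != len(seq):
        v.append("repeated cell within a sequence")
    if any(c < 0 or c >= sch.CORSI_GRID_CELLS for c in seq):
        v.append("cell index outside the 4x4 grid")
    return v


def validate_memorability_block(block: sch.MemorabilityBlock) -> list[str]:
    v: list[str] = []
    order = block.presentation_order
    counts: dict[str, int] = {}
    for img in order:
        counts[img] = counts.get(img, 0) + 1
    targets = [i for i, r in block.roles.items() if r == "target"]
    fillers = [i for i, r in block.roles.items() if r == "filler"]
    if len(targets) != sch.MEM_N_TARGETS:
        v.append(f"{len(targets)} targets, expected 40")
    if len(fillers) != sch.MEM_N_FILLERS:
        v.append(f"{len(fillers)} fillers, expected 40")
    if len(order) != sch.MEM_N_TARGETS * 2 + sch.MEM_N_FILLERS:
        v.append(f"{len(order)} presentations, expected 120")
    for t in targets:
        if counts.get(t) != 2:
            v.append(f"target {t} shown {counts.get(t, 0)} times")
    for f in fillers:
        if counts.get(f) != 1:
            v.append(f"filler {f} shown {counts.get(f, 0)} times")
    # recompute distances from the order itself
    n_long = n_short = 0
    for t in targets:
        idx = [i for i, img in enumerate(order) if img == t]
        if len(idx) != 2:
            continue
        d = idx[1] - idx[0]
        if block.repeat_distance.get(t) != d:
            v.append(f"target {t}: stored distance {block.repeat_distance.get(t)} != {d}")
        if sch.MEM_LONG_RANGE[0] <= d <= sch.MEM_LONG_RANGE[1]:
            n_long += 1
        elif sch.MEM_SHORT_RANGE[0] <= d <= sch.MEM_SHORT_RANGE[1]:
            n_short += 1
        else:
            v.append(f"target {t}: distance {d} in neither the short nor long band")
    if n_long != sch.MEM_N_LONG:
        v.append(f"{n_long} long-distance targets, expected 8")
    if n_short != sch.MEM_N_SHORT:
        v.append(f"{n_short} short-distance targets, expected 32")
    return v


_VALIDATORS = {
    "mot": validate_mot_trial,
    "enumeration": validate_enumeration_trial,
    "lib": validate_lib_trial,
    "gonogo": validate_gonogo_trial,
    "corsi": validate_corsi_trial,
    "memorability": validate_memorability_block,
}


def validate_trial(task: str, trial) -> list[str]:
    """Validate a single emitted trial (or block) of the given task.

    Switch trials are validated at the session level because the
    switch/repeat flag is defined relative to the previous trial; use
    :func:`validate_switch_session`.
    """
    if task == "switch":
        raise ValueError("switch trials are validated per session")
    try:
        validator = _VALIDATORS[task]
    except KeyError:
        raise ValueError(f"unknown task {task!r}") from None
    return validator(trial)


def check(task: str, trial) -> None:
    """Raise ValidationError if the schedule violates any invariant."""
    violations = (
        validate_switch_session(trial) if task == "switch" else validate_trial(task, trial)
    )
    if violations:
        raise ValidationError(f"{task}: " + "; ".join(violations))
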