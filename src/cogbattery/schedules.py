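"""Seeded trial-schedule generators for the seven battery tasks.

Every generator is a pure function of its parameters and an integer seed:
identical calls produce identical schedules.  Geometry is expressed in
degrees of visual angle with the origin at the screen centre and y
increasing upward; durations are milliseconds unless a field name says
otherwise.  Structural invariants of each schedule type are checked
independently in :mod:`cogbattery.validate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError

TASKS = (
    "mot",
    "enumeration",
    "lib",
    "gonogo",
    "switch",
    "corsi",
    "memorability",
)

# ---------------------------------------------------------------------------
# Multiple-object tracking
# ---------------------------------------------------------------------------

MOT_CANVAS_DEG = 12.0
MOT_DISC_DIAMETER_DEG = 1.2
MOT_N_DISCS = 10
MOT_N_TARGETS = 5
MOT_DURATION_S = 8.0
MOT_SPEEDS = (1.0, 4.0, 8.0)
DEFAULT_FRAME_RATE = 60.0


@dataclass
class MotTrial:
    """One tracking trial: full disc trajectories plus the cued target set.

    ``disc_positions`` has shape (n_frames, n_discs, 2); frame 0 is the
    configuration at motion onset.  Discs move in straight lines at constant
    speed and reflect specularly off the canvas walls; disc-disc occlusion
    is permitted.
    """

    disc_positions: np.ndarray
    target_indices: list[int]
    speed: float
    frame_rate: float = DEFAULT_FRAME_RATE
    canvas: float = MOT_CANVAS_DEG
    disc_diameter: float = MOT_DISC_DIAMETER_DEG

    @property
    def condition(self) -> str:
        return f"speed{self.speed:g}"

    def to_payload(self) -> dict:
        return {
            "disc_positions": np.round(self.disc_positions, 6).tolist(),
            "target_indices": list(self.target_indices),
            "speed": self.speed,
            "frame_rate": self.frame_rate,
            "canvas": self.canvas,
            "disc_diameter": self.disc_diameter,
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "MotTrial":
        return cls(
            disc_positions=np.asarray(payload["disc_positions"], dtype=float),
            target_indices=list(payload["target_indices"]),
            speed=float(payload["speed"]),
            frame_rate=float(payload["frame_rate"]),
            canvas=float(payload["canvas"]),
            disc_diameter=float(payload["disc_diameter"]),
        )


def _place_separated(
    rng: np.random.Generator,
    n: int,
    bound: float,
    min_sep: float,
    budget: int = 20000,
) -> np.ndarray:
    """Uniform points in the square [-bound, bound]^2 with pairwise separation."""
    points: list[np.ndarray] = []
    attempts = 0
    while len(points) < n:
        if attempts >= budget:
            raise GenerationError(
                f"could not place {n} separated points within {budget} attempts"
            )
        attempts += 1
        p = rng.uniform(-bound, bound, size=2)
        if all(np.hypot(*(p - q)) >= min_sep for q in points):
            points.append(p)
    return np.array(points)


def generate_mot_trial(
    speed: float,
    seed: int,
    frame_rate: float = DEFAULT_FRAME_RATE,
    duration_s: float = MOT_DURATION_S,
    n_discs: int = MOT_N_DISCS,
    n_targets: int = MOT_N_TARGETS,
) -> MotTrial:
    """Generate one tracking trial.

    Parameters
    ----------
    speed:
        Disc speed in degrees/s (the battery uses 1, 4 or 8, but any
        positive value is accepted).
    seed:
        Seed for the trial's private random generator.
    """
    if speed <= 0:
        raise ValueError(f"speed must be positive, got {speed}")
    if frame_rate <= 0:
        raise ValueError(f"frame_rate must be positive, got {frame_rate}")
    rng = np.random.default_rng(seed)
    radius = MOT_DISC_DIAMETER_DEG / 2.0
    bound = MOT_CANVAS_DEG / 2.0 - radius  # disc stays entirely on canvas
    n_frames = int(round(duration_s * frame_rate)) + 1

    pos0 = _place_separated(rng, n_discs, bound, MOT_DISC_DIAMETER_DEG)
    angles = rng.uniform(0.0, 2.0 * math.pi, size=n_discs)
    vel = speed / frame_rate * np.column_stack([np.cos(angles), np.sin(angles)])

    # free-flight positions folded into [-bound, bound] by a triangle wave,
    # which is exactly specular reflection at the walls
    t = np.arange(n_frames)[:, None, None]
    free = pos0[None] + vel[None] * t
    period = 4.0 * bound
    y = np.mod(free + bound, period)
    traj = np.where(y < 2.0 * bound, y - bound, 3.0 * bound - y)

    targets = sorted(rng.choice(n_discs, size=n_targets, replace=False).tolist())
    return MotTrial(
        disc_positions=traj,
        target_indices=targets,
        speed=float(speed),
        frame_rate=float(frame_rate),
    )


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

ENUM_SET_SIZES = (5, 6, 7, 8, 9)
ENUM_CIRCLE_DIAMETER_DEG = 0.5
ENUM_REGION_DIAMETER_DEG = 5.0
ENUM_EXPOSURE_MS = 50
ENUM_TRIALS_PER_CONDITION = 20


@dataclass
class EnumerationTrial:
    """A brief flash of ``n_circles`` non-overlapping white circles."""

    circle_centers: np.ndarray  # (n, 2), degrees
    n_circles: int
    circle_diameter: float = ENUM_CIRCLE_DIAMETER_DEG
    region_diameter: float = ENUM_REGION_DIAMETER_DEG
    exposure_ms: int = ENUM_EXPOSURE_MS

    @property
    def condition(self) -> str:
        return f"set{self.n_circles}"

    def to_payload(self) -> dict:
        return {
            "circle_centers": np.round(self.circle_centers, 6).tolist(),
            "n_circles": self.n_circles,
            "circle_diameter": self.circle_diameter,
            "region_diameter": self.region_diameter,
            "exposure_ms": self.exposure_ms,
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "EnumerationTrial":
        return cls(
            circle_centers=np.asarray(payload["circle_centers"], dtype=float),
            n_circles=int(payload["n_circles"]),
            circle_diameter=float(payload["circle_diameter"]),
            region_diameter=float(payload["region_diameter"]),
            exposure_ms=int(payload["exposure_ms"]),
        )


def generate_enumeration_trial(
    n_circles: int, seed: int, budget: int = 20000
) -> EnumerationTrial:
    """Rejection-sample a non-overlapping circle layout inside the 5 deg region."""
    if n_circles < 1:
        raise ValueError(f"n_circles must be >= 1, got {n_circles}")
    rng = np.random.default_rng(seed)
    r_outer = ENUM_REGION_DIAMETER_DEG / 2.0 - ENUM_CIRCLE_DIAMETER_DEG / 2.0
    min_sep = ENUM_CIRCLE_DIAMETER_DEG
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_circles:
        if attempts >= budget:
            raise GenerationError(
                f"could not place {n_circles} circles within rejection "
                f"budget of {budget} samples"
            )
        attempts += 1
        rad = r_outer * math.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        p = np.array([rad * math.cos(theta), rad * math.sin(theta)])
        if all(np.hypot(*(p - q)) >= min_sep for q in centers):
            centers.append(p)
    return EnumerationTrial(circle_centers=np.array(centers), n_circles=n_circles)


# ---------------------------------------------------------------------------
# Load-induced blindness (dual task)
# ---------------------------------------------------------------------------

LIB_ECCENTRICITIES = (3.0, 6.0)
LIB_CROSS_LENGTHS = (0.5, 1.0)
LIB_TARGET_CONTRAST = 0.8
LIB_NONTARGET_CONTRAST = 0.4
LIB_GABOR_SIGMA = 0.7
LIB_SPATIAL_FREQ = 2.2
LIB_EXPOSURE_MS = 50
LIB_TRIALS_PER_CONDITION = 20


@dataclass
class LibTrial:
    """Foveal cross-length judgment plus peripheral contrast-increment detection.

    Four Gabor patches sit on the diagonals at the trial's eccentricity;
    exactly one (the target quadrant) carries the enhanced contrast.
    """

    cross_lengths: dict  # {"vertical": deg, "horizontal": deg}
    gabor_eccentricity: float
    gabor_positions: np.ndarray  # (4, 2)
    target_quadrant: int
    contrasts: list[float]
    gabor_sigma: float = LIB_GABOR_SIGMA
    spatial_freq: float = LIB_SPATIAL_FREQ
    exposure_ms: int = LIB_EXPOSURE_MS

    @property
    def cross_long_axis(self) -> str:
        v, h = self.cross_lengths["vertical"], self.cross_lengths["horizontal"]
        return "vertical" if v > h else "horizontal"

    @property
    def condition(self) -> str:
        return "near" if self.gabor_eccentricity <= 4.5 else "far"

    def to_payload(self) -> dict:
        return {
            "cross_lengths": dict(self.cross_lengths),
            "gabor_eccentricity": self.gabor_eccentricity,
            "gabor_positions": np.round(self.gabor_positions, 6).tolist(),
            "target_quadrant": self.target_quadrant,
            "contrasts": list(self.contrasts),
            "gabor_sigma": self.gabor_sigma,
            "spatial_freq": self.spatial_freq,
            "exposure_ms": self.exposure_ms,
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "LibTrial":
        return cls(
            cross_lengths={k: float(v) for k, v in payload["cross_lengths"].items()},
            gabor_eccentricity=float(payload["gabor_eccentricity"]),
            gabor_positions=np.asarray(payload["gabor_positions"], dtype=float),
            target_quadrant=int(payload["target_quadrant"]),
            contrasts=[float(c) for c in payload["contrasts"]],
            gabor_sigma=float(payload["gabor_sigma"]),
            spatial_freq=float(payload["spatial_freq"]),
            exposure_ms=int(payload["exposure_ms"]),
        )


def generate_lib_trial(eccentricity: float, seed: int) -> LibTrial:
    """Generate one dual-task trial at the given Gabor eccentricity (deg)."""
    if eccentricity <= 0:
        raise ValueError(f"eccentricity must be positive, got {eccentricity}")
    rng = np.random.default_rng(seed)
    long_axis = rng.choice(["vertical", "horizontal"])
    lengths = {
        "vertical": max(LIB_CROSS_LENGTHS) if long_axis == "vertical" else min(LIB_CROSS_LENGTHS),
        "horizontal": max(LIB_CROSS_LENGTHS) if long_axis == "horizontal" else min(LIB_CROSS_LENGTHS),
    }
    # quadrants 0..3 anticlockwise from upper-right; patches on the diagonals
    diag = eccentricity / math.sqrt(2.0)
    positions = np.array(
        [[diag, diag], [-diag, diag], [-diag, -diag], [diag, -diag]]
    )
    target = int(rng.integers(4))
    contrasts = [LIB_NONTARGET_CONTRAST] * 4
    contrasts[target] = LIB_TARGET_CONTRAST
    return LibTrial(
        cross_lengths=lengths,
        gabor_eccentricity=float(eccentricity),
        gabor_positions=positions,
        target_quadrant=target,
        contrasts=contrasts,
    )


# ---------------------------------------------------------------------------
# Go/no-go (cued continuous performance)
# ---------------------------------------------------------------------------

GONOGO_CUE = 7
GONOGO_GO_PROBE = 3
GONOGO_EXPOSURE_MS = 50
GONOGO_ISI_MS = 950
GONOGO_TRIALS_PER_TYPE = 18


@dataclass
class GoNoGoTrial:
    """A digit stream containing exactly one cue (7) followed by the probe.

    The trial is a go trial iff the probe is 3.
    """

    digit_stream: list[int]
    probe_digit: int
    is_go: bool
    exposure_ms: int = GONOGO_EXPOSURE_MS
    isi_ms: int = GONOGO_ISI_MS

    @property
    def condition(self) -> str:
        return "go" if self.is_go else "nogo"

    def to_payload(self) -> dict:
        return {
            "digit_stream": list(self.digit_stream),
            "probe_digit": self.probe_digit,
            "is_go": self.is_go,
            "exposure_ms": self.exposure_ms,
            "isi_ms": self.isi_ms,
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "GoNoGoTrial":
        return cls(
            digit_stream=[int(d) for d in payload["digit_stream"]],
            probe_digit=int(payload["probe_digit"]),
            is_go=bool(payload["is_go"]),
            exposure_ms=int(payload["exposure_ms"]),
            isi_ms=int(payload["isi_ms"]),
        )


def _gonogo_trial(rng: np.random.Generator, is_go: bool) -> GoNoGoTrial:
    n_fillers = int(rng.integers(2, 6))  # 2..5 digits before the cue
    non_cue = [d for d in range(10) if d != GONOGO_CUE]
    fillers = rng.choice(non_cue, size=n_fillers, replace=True).tolist()
    if is_go:
        probe = GONOGO_GO_PROBE
    else:
        probe = int(rng.choice([d for d in non_cue if d != GONOGO_GO_PROBE]))
    stream = [int(d) for d in fillers] + [GONOGO_CUE, probe]
    return GoNoGoTrial(digit_stream=stream, probe_digit=probe, is_go=is_go)


def generate_gonogo_session(
    n_go: int = GONOGO_TRIALS_PER_TYPE,
    n_nogo: int = GONOGO_TRIALS_PER_TYPE,
    seed: int = 0,
) -> list[GoNoGoTrial]:
    """Balanced-by-design session: exactly n_go go and n_nogo no-go trials,
    shuffled."""
    if n_go < 0 or n_nogo < 0:
        raise ValueError("trial counts must be non-negative")
    rng = np.random.default_rng(seed)
    labels = np.array([True] * n_go + [False] * n_nogo)
    rng.shuffle(labels)
    return [_gonogo_trial(rng, bool(g)) for g in labels]


# ---------------------------------------------------------------------------
# Task switching (task-cueing paradigm)
# ---------------------------------------------------------------------------

SWITCH_CUES = ("blue_diamond", "red_square")
SWITCH_DIGITS = (1, 2, 3, 4, 6, 7, 8, 9)
SWITCH_CUE_LEAD_MS = 650
SWITCH_TRIALS_PER_TASK = 30
SWITCH_N_PRACTICE = 20


def switch_correct_key(cue: str, digit: int) -> str:
    """Response-rule table: blue diamond cues odd/even (odd->F, even->J);
    red square cues higher/lower than five (higher->F, lower->J)."""
    if cue == "blue_diamond":
        return "F" if digit % 2 == 1 else "J"
    if cue == "red_square":
        return "F" if digit > 5 else "J"
    raise ValueError(f"unknown cue {cue!r}")


@dataclass
class SwitchTrial:
    cue: str
    digit: int
    correct_key: str
    is_switch: bool | None  # None for the very first trial
    is_practice: bool
    cue_lead_ms: int = SWITCH_CUE_LEAD_MS

    @property
    def task_type(self) -> str:
        return "odd_even" if self.cue == "blue_diamond" else "high_low"

    @property
    def condition(self) -> str:
        return self.task_type

    def to_payload(self) -> dict:
        return {
            "cue": self.cue,
            "digit": self.digit,
            "correct_key": self.correct_key,
            "is_switch": self.is_switch,
            "is_practice": self.is_practice,
            "cue_lead_ms": self.cue_lead_ms,
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "SwitchTrial":
        return cls(
            cue=str(payload["cue"]),
            digit=int(payload["digit"]),
            correct_key=str(payload["correct_key"]),
            is_switch=None if payload["is_switch"] is None else bool(payload["is_switch"]),
            is_practice=bool(payload["is_practice"]),
            cue_lead_ms=int(payload["cue_lead_ms"]),
        )


def generate_switch_session(
    n_per_task: int = SWITCH_TRIALS_PER_TASK,
    n_practice: int = SWITCH_N_PRACTICE,
    seed: int = 0,
) -> list[SwitchTrial]:
    """Practice trials (uniform random cue) followed by a main phase with an
    exact per-task cue count; switch/repeat status is derived post hoc from
    the realised cue sequence."""
    if n_per_task < 0 or n_practice < 0:
        raise ValueError("trial counts must be non-negative")
    rng = np.random.default_rng(seed)
    practice_cues = rng.choice(SWITCH_CUES, size=n_practice, replace=True).tolist()
    main_cues = np.array([SWITCH_CUES[0]] * n_per_task + [SWITCH_CUES[1]] * n_per_task)
    rng.shuffle(main_cues)
    cues = practice_cues + main_cues.tolist()

    trials: list[SwitchTrial] = []
    prev_cue: str | None = None
    for i, cue in enumerate(cues):
        digit = int(rng.choice(SWITCH_DIGITS))
        trials.append(
            SwitchTrial(
                cue=cue,
                digit=digit,
                correct_key=switch_correct_key(cue, digit),
                is_switch=None if prev_cue is None else cue != prev_cue,
                is_practice=i < n_practice,
            )
        )
        prev_cue = cue
    return trials


# ---------------------------------------------------------------------------
# Working memory (Corsi block tapping, 4x4 grid)
# ---------------------------------------------------------------------------

CORSI_GRID_CELLS = 16
CORSI_LENGTHS = (4, 5, 6, 7, 8)
CORSI_FLASH_MS = 900
CORSI_CELL_SIZE_DEG = 2.0
CORSI_TRIALS_PER_LENGTH = 12


@dataclass
class CorsiTrial:
    """One flashed cell sequence on the 4x4 grid (cells indexed 0..15)."""

    flash_sequence: list[int]
    length: int
    flash_ms: int = CORSI_FLASH_MS
    cell_size: float = CORSI_CELL_SIZE_DEG

    @property
    def condition(self) -> str:
        return f"len{self.length}"

    def to_payload(self) -> dict:
        return {
            "flash_sequence": list(self.flash_sequence),
            "length": self.length,
            "flash_ms": self.flash_ms,
            "cell_size": self.cell_size,
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "CorsiTrial":
        return cls(
            flash_sequence=[int(c) for c in payload["flash_sequence"]],
            length=int(payload["length"]),
            flash_ms=int(payload["flash_ms"]),
            cell_size=float(payload["cell_size"]),
        )


def generate_corsi_session(
    lengths: tuple[int, ...] = CORSI_LENGTHS,
    trials_per_length: int = CORSI_TRIALS_PER_LENGTH,
    seed: int = 0,
) -> list[CorsiTrial]:
    """Pseudo-randomly interleaved span trials; cells within a sequence are
    distinct (classic Corsi convention)."""
    lengths = tuple(int(l) for l in lengths)
    if any(l < 1 or l > CORSI_GRID_CELLS for l in lengths):
        raise ValueError(f"sequence lengths must be in 1..{CORSI_GRID_CELLS}")
    if trials_per_length < 0:
        raise ValueError("trials_per_length must be non-negative")
    rng = np.random.default_rng(seed)
    schedule = np.repeat(lengths, trials_per_length)
    rng.shuffle(schedule)
    return [
        CorsiTrial(
            flash_sequence=rng.permutation(CORSI_GRID_CELLS)[:length].tolist(),
            length=int(length),
        )
        for length in schedule
    ]


# ---------------------------------------------------------------------------
# Memorability (repeat detection in a natural-image stream)
# ---------------------------------------------------------------------------

MEM_N_TARGETS = 40
MEM_N_FILLERS = 40
MEM_N_LONG = 8
MEM_N_SHORT = 32
MEM_LONG_RANGE = (100, 109)
MEM_SHORT_RANGE = (2, 5)
MEM_EXPOSURE_MS = 1000
MEM_FEEDBACK_MS = 1400
MEM_HIT_RATE_WINDOW = (0.60, 0.70)
MEM_CATEGORIES = ("bedroom", "kitchen")
MEM_RESTART_BUDGET = 1000


@dataclass
class ImageRecord:
    """Catalog entry standing in for a natural-scene photograph: an ID, its
    scene category, and a nominal population hit rate (memorability score)."""

    image_id: str
    category: str
    hit_rate: float


def make_synthetic_catalog(
    n_per_category: int = 100,
    categories: tuple[str, ...] = MEM_CATEGORIES,
    seed: int = 0,
) -> list[ImageRecord]:
    """Synthetic image catalog with intermediate-memorability annotations.

    Stands in for a curated natural-scene image set; hit rates are drawn
    uniformly from the intermediate window [0.60, 0.70].
    """
    rng = np.random.default_rng(seed)
    lo, hi = MEM_HIT_RATE_WINDOW
    catalog = []
    for cat in categories:
        for i in range(n_per_category):
            catalog.append(
                ImageRecord(
                    image_id=f"{cat}_{i:04d}",
                    category=cat,
                    hit_rate=float(rng.uniform(lo, hi)),
                )
            )
    return catalog


@dataclass
class MemorabilityBlock:
    """One 120-presentation block: 40 targets shown twice, 40 fillers once.

    ``repeat_distance`` maps each target ID to the difference of its two
    presentation indices; 8 targets repeat at a long distance (100-109
    intervening positions counted as index difference) and 32 at a short
    distance (2-5).
    """

    presentation_order: list[str]
    roles: dict  # image_id -> "target" | "filler"
    repeat_distance: dict  # target image_id -> int
    category: str
    hit_rates: dict = field(default_factory=dict)  # image_id -> nominal hit rate
    exposure_ms: int = MEM_EXPOSURE_MS
    feedback_ms: int = MEM_FEEDBACK_MS

    @property
    def condition(self) -> str:
        return self.category

    def distance_class(self, image_id: str) -> str | None:
        d = self.repeat_distance.get(image_id)
        if d is None:
            return None
        return "long" if d >= MEM_LONG_RANGE[0] else "short"

    def to_payload(self) -> dict:
        return {
            "presentation_order": list(self.presentation_order),
            "roles": dict(self.roles),
            "repeat_distance": dict(self.repeat_distance),
            "category": self.category,
            "hit_rates": {k: float(v) for k, v in self.hit_rates.items()},
            "exposure_ms": self.exposure_ms,
            "feedback_ms": self.feedback_ms,
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "MemorabilityBlock":
        return cls(
            presentation_order=list(payload["presentation_order"]),
            roles=dict(payload["roles"]),
            repeat_distance={k: int(v) for k, v in payload["repeat_distance"].items()},
            category=str(payload["category"]),
            hit_rates={k: float(v) for k, v in payload.get("hit_rates", {}).items()},
            exposure_ms=int(payload["exposure_ms"]),
            feedback_ms=int(payload["feedback_ms"]),
        )


def _try_place_block(rng: np.random.Generator, n_slots: int) -> list[tuple[int, int]] | None:
    """One randomized attempt to slot 8 long-distance and 32 short-distance
    target pairs into ``n_slots`` positions.  Returns the pair list or None
    on a dead end."""
    free = np.ones(n_slots, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for n_pairs, (dlo, dhi) in ((MEM_N_LONG, MEM_LONG_RANGE), (MEM_N_SHORT, MEM_SHORT_RANGE)):
        for _ in range(n_pairs):
            candidates = [
                (i, i + d)
                for i in np.flatnonzero(free)
                for d in range(dlo, dhi + 1)
                if i + d < n_slots and free[i + d]
            ]
            if not candidates:
                return None
            i, j = candidates[rng.integers(len(candidates))]
            free[i] = free[j] = False
            pairs.append((int(i), int(j)))
    return pairs


def generate_memorability_block(
    catalog: list[ImageRecord],
    category: str,
    seed: int,
    restart_budget: int = MEM_RESTART_BUDGET,
) -> MemorabilityBlock:
    """Schedule one repeat-detection block by randomized constraint
    satisfaction with restarts."""
    lo, hi = MEM_HIT_RATE_WINDOW
    pool = [
        rec
        for rec in catalog
        if rec.category == category and lo <= rec.hit_rate <= hi
    ]
    n_needed = MEM_N_TARGETS + MEM_N_FILLERS
    if len(pool) < n_needed:
        raise ValueError(
            f"catalog holds {len(pool)} eligible {category!r} images; "
            f"{n_needed} required"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_needed, replace=False)
    images = [pool[i] for i in chosen]
    targets, fillers = images[:MEM_N_TARGETS], images[MEM_N_TARGETS:]

    n_slots = MEM_N_TARGETS * 2 + MEM_N_FILLERS
    pairs = None
    for _ in range(restart_budget):
        pairs = _try_place_block(rng, n_slots)
        if pairs is not None:
            break
    if pairs is None:
        raise GenerationError(
            f"memorability block placement exhausted restart budget of {restart_budget}"
        )

    order: list[str | None] = [None] * n_slots
    repeat_distance: dict[str, int] = {}
    for rec, (i, j) in zip(targets, pairs):
        order[i] = rec.image_id
        order[j] = rec.image_id
        repeat_distance[rec.image_id] = j - i
    free_slots = [s for s in range(n_slots) if order[s] is None]
    for rec, s in zip(fillers, free_slots):
        order[s] = rec.image_id

    roles = {rec.image_id: "target" for rec in targets}
    roles.update({rec.image_id: "filler" for rec in fillers})
    return MemorabilityBlock(
        presentation_order=[s for s in order if s is not None],
        roles=roles,
        repeat_distance=repeat_distance,
        category=category,
        hit_rates={rec.image_id: rec.hit_rate for rec in images},
    )


TRIAL_TYPES = {
    "mot": MotTrial,
    "enumeration": EnumerationTrial,
    "lib": LibTrial,
    "gonogo": GoNoGoTrial,
    "switch": SwitchTrial,
    "corsi": CorsiTrial,
    "memorability": MemorabilityBlock,
}
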