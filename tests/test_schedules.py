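"""Structural and statistical tests of the seven trial-schedule generators."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cogbattery import schedules as sch
from cogbattery import validate
from cogbattery.errors import GenerationError


def _payload_json(trial):
    return json.dumps(trial.to_payload(), sort_keys=True)


@pytest.mark.parametrize(
    "make",
    [
        lambda seed: sch.generate_mot_trial(4.0, seed),
        lambda seed: sch.generate_enumeration_trial(7, seed),
        lambda seed: sch.generate_lib_trial(3.0, seed),
        lambda seed: sch.generate_gonogo_session(seed=seed),
        lambda seed: sch.generate_switch_session(seed=seed),
        lambda seed: sch.generate_corsi_session(seed=seed),
        lambda seed: sch.generate_memorability_block(
            sch.make_synthetic_catalog(seed=0), "kitchen", seed
        ),
    ],
    ids=["mot", "enumeration", "lib", "gonogo", "switch", "corsi", "memorability"],
)
def test_generators_are_pure_functions_of_seed(make):
    a, b = make(123), make(123)
    if isinstance(a, list):
        assert [_payload_json(t) for t in a] == [_payload_json(t) for t in b]
    else:
        assert _payload_json(a) == _payload_json(b)
    c = make(124)
    if isinstance(a, list):
        assert [_payload_json(t) for t in a] != [_payload_json(t) for t in c]
    else:
        assert _payload_json(a) != _payload_json(c)


# ---------------------------------------------------------------------------
# MOT
# ---------------------------------------------------------------------------


def test_mot_trial_structure_and_bounds():
    trial = sch.generate_mot_trial(speed=4.0, seed=1)
    n_frames = int(sch.MOT_DURATION_S * sch.DEFAULT_FRAME_RATE) + 1
    assert trial.disc_positions.shape == (n_frames, 10, 2)
    assert len(trial.target_indices) == 5
    assert np.all(np.abs(trial.disc_positions) <= 6.0)
    assert validate.validate_mot_trial(trial) == []


@pytest.mark.parametrize("speed", [1.0, 4.0, 8.0])
def test_mot_speed_recoverable_from_trajectory(speed):
    """Median per-frame displacement x frame rate recovers the input speed."""
    for seed in range(5):
        trial = sch.generate_mot_trial(speed, seed)
        assert validate.infer_mot_speed(trial) == pytest.approx(speed, abs=1e-3)


def test_mot_nonbounce_displacement_equals_speed_over_framerate():
    trial = sch.generate_mot_trial(speed=8.0, seed=3)
    step = trial.speed / trial.frame_rate
    disp = np.linalg.norm(np.diff(trial.disc_positions, axis=0), axis=2)
    # displacement is either a full step (free flight) or shorter (bounce)
    assert np.all(disp <= step + 1e-9)
    frac_full = np.mean(np.abs(disp - step) < 1e-9)
    assert frac_full > 0.9  # bounces are rare at these speeds


def test_mot_zero_speed_limit_freezes_discs():
    trial = sch.generate_mot_trial(speed=1e-12, seed=2)
    assert np.allclose(trial.disc_positions, trial.disc_positions[0], atol=1e-8)


def test_mot_initial_positions_separated():
    trial = sch.generate_mot_trial(speed=4.0, seed=9)
    p0 = trial.disc_positions[0]
    d = np.linalg.norm(p0[:, None] - p0[None], axis=2)
    np.fill_diagonal(d, np.inf)
    assert d.min() >= sch.MOT_DISC_DIAMETER_DEG - 1e-9


@pytest.mark.parametrize("speed,frame_rate", [(0.0, 60.0), (-1.0, 60.0), (4.0, 0.0)])
def test_mot_rejects_nonpositive_parameters(speed, frame_rate):
    with pytest.raises(ValueError):
        sch.generate_mot_trial(speed=speed, seed=0, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


def test_enumeration_layout_respects_min_distance():
    trial = sch.generate_enumeration_trial(9, seed=7)
    assert trial.circle_centers.shape == (9, 2)
    d = np.linalg.norm(
        trial.circle_centers[:, None] - trial.circle_centers[None], axis=2
    )
    np.fill_diagonal(d, np.inf)
    assert d.min() >= 0.5


def test_enumeration_single_circle_inside_region():
    trial = sch.generate_enumeration_trial(1, seed=0)
    assert np.hypot(*trial.circle_centers[0]) <= 2.5


def test_enumeration_mass_generation_never_violates_constraints():
    """Independent O(n^2) checker over thousands of layouts."""
    rng = np.random.default_rng(0)
    for _ in range(2000):
        n = int(rng.integers(5, 10))
        trial = sch.generate_enumeration_trial(n, int(rng.integers(2**31)))
        assert validate.validate_enumeration_trial(trial) == []


def test_enumeration_unplaceable_count_names_budget():
    with pytest.raises(GenerationError, match="budget"):
        sch.generate_enumeration_trial(500, seed=0, budget=2000)


# ---------------------------------------------------------------------------
# Load-induced blindness
# ---------------------------------------------------------------------------


def test_lib_trial_contrast_and_geometry():
    for ecc in (3.0, 6.0):
        trial = sch.generate_lib_trial(ecc, seed=3)
        assert validate.validate_lib_trial(trial) == []
        assert sorted(trial.contrasts) == [0.4, 0.4, 0.4, 0.8]
        assert set(trial.cross_lengths.values()) == {0.5, 1.0}
        assert trial.cross_lengths["vertical"] != trial.cross_lengths["horizontal"]


def test_lib_target_quadrant_uniform_over_seeds():
    counts = np.zeros(4)
    for seed in range(4000):
        counts[sch.generate_lib_trial(6.0, seed).target_quadrant] += 1
    assert stats.chisquare(counts).pvalue > 0.001


# ---------------------------------------------------------------------------
# Go/no-go
# ---------------------------------------------------------------------------


def test_gonogo_default_session_is_balanced():
    trials = sch.generate_gonogo_session(seed=5)
    assert len(trials) == 36
    assert sum(t.is_go for t in trials) == 18


def test_gonogo_all_nogo_session():
    trials = sch.generate_gonogo_session(0, 5, seed=1)
    assert len(trials) == 5 and not any(t.is_go for t in trials)


def test_gonogo_stream_microstructure():
    """Exhaustive scan: one cue, probe follows it, no-go probes never 3,
    filler run length 2-5 with no premature cue."""
    for seed in range(200):
        for t in sch.generate_gonogo_session(seed=seed):
            assert validate.validate_gonogo_trial(t) == []
            cue_at = t.digit_stream.index(7)
            assert 2 <= cue_at <= 5
            assert all(d != 7 for d in t.digit_stream[:cue_at])
            if not t.is_go:
                assert t.probe_digit in {0, 1, 2, 4, 5, 6, 8, 9}


# ---------------------------------------------------------------------------
# Task switching
# ---------------------------------------------------------------------------


def test_switch_default_session_counts():
    trials = sch.generate_switch_session(seed=2)
    assert len(trials) == 80
    practice = [t for t in trials if t.is_practice]
    main = [t for t in trials if not t.is_practice]
    assert len(practice) == 20 and len(main) == 60
    assert sum(t.cue == "blue_diamond" for t in main) == 30


def test_switch_minimal_session_forces_alternation():
    trials = sch.generate_switch_session(n_per_task=1, n_practice=0, seed=0)
    assert len(trials) == 2
    assert trials[0].is_switch is None
    assert trials[1].is_switch is True


def test_switch_keys_match_independent_rule_table():
    """Recompute the correct key from a hand-written rule table."""
    oracle = {}
    for d in (1, 2, 3, 4, 6, 7, 8, 9):
        oracle[("blue_diamond", d)] = "F" if d in (1, 3, 7, 9) else "J"
        oracle[("red_square", d)] = "F" if d in (6, 7, 8, 9) else "J"
    for seed in range(20):
        trials = sch.generate_switch_session(seed=seed)
        assert validate.validate_switch_session(trials) == []
        for t in trials:
            assert t.correct_key == oracle[(t.cue, t.digit)]


# ---------------------------------------------------------------------------
# Corsi
# ---------------------------------------------------------------------------


def test_corsi_default_session_counts():
    trials = sch.generate_corsi_session(seed=4)
    assert len(trials) == 60
    for length in (4, 5, 6, 7, 8):
        assert sum(t.length == length for t in trials) == 12
    assert all(validate.validate_corsi_trial(t) == [] for t in trials)


def test_corsi_full_grid_sequence_is_permutation():
    trials = sch.generate_corsi_session(lengths=(16,), trials_per_length=1, seed=0)
    assert sorted(trials[0].flash_sequence) == list(range(16))


def test_corsi_rejects_overlong_sequences():
    with pytest.raises(ValueError):
        sch.generate_corsi_session(lengths=(17,), seed=0)


def test_corsi_flashed_cells_uniform_over_grid():
    counts = np.zeros(16)
    trials = sch.generate_corsi_session(
        lengths=(5,), trials_per_length=2000, seed=8
    )
    for t in trials:
        for c in t.flash_sequence:
            counts[c] += 1
    assert stats.chisquare(counts).pvalue > 0.001


# ---------------------------------------------------------------------------
# Memorability
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def catalog():
    return sch.make_synthetic_catalog(seed=0)


def test_memorability_block_composition(catalog):
    block = sch.generate_memorability_block(catalog, "bedroom", seed=1)
    assert len(block.presentation_order) == 120
    assert len(set(block.presentation_order)) == 80
    assert validate.validate_memorability_block(block) == []


def test_memorability_distances_match_index_difference_oracle(catalog):
    block = sch.generate_memorability_block(catalog, "kitchen", seed=6)
    for image_id, stored in block.repeat_distance.items():
        idx = [i for i, im in enumerate(block.presentation_order) if im == image_id]
        assert len(idx) == 2
        assert idx[1] - idx[0] == stored
    n_long = sum(1 for d in block.repeat_distance.values() if 100 <= d <= 109)
    n_short = sum(1 for d in block.repeat_distance.values() if 2 <= d <= 5)
    assert (n_long, n_short) == (8, 32)


def test_memorability_insufficient_catalog_rejected(catalog):
    small = [r for r in catalog if r.category == "bedroom"][:79]
    with pytest.raises(ValueError, match="eligible"):
        sch.generate_memorability_block(small, "bedroom", seed=0)


def test_memorability_scheduler_succeeds_on_nearly_all_seeds(catalog):
    failures = sum(
        1
        for seed in range(1000)
        if _block_fails(catalog, seed)
    )
    assert failures <= 10  # >= 99% success with the default restart budget


def _block_fails(catalog, seed) -> bool:
    try:
        sch.generate_memorability_block(catalog, "bedroom", seed)
        return False
    except GenerationError:
        return True


# ---------------------------------------------------------------------------
# Serialization round trips
# ---------------------------------------------------------------------------


@settings(max_examples=15, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_trial_payload_round_trip(seed):
    for make, cls in [
        (lambda s: sch.generate_mot_trial(4.0, s), sch.MotTrial),
        (lambda s: sch.generate_enumeration_trial(6, s), sch.EnumerationTrial),
        (lambda s: sch.generate_lib_trial(3.0, s), sch.LibTrial),
    ]:
        trial = make(seed)
        again = cls.from_payload(json.loads(json.dumps(trial.to_payload())))
        assert _payload_json(again) == _payload_json(trial)
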