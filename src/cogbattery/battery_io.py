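"""Pinned file formats and configuration.

* trial schedules: JSON Lines, one object per trial with fields
  ``{task, trial_index, condition, payload}``;
* sessions: tidy CSV, one row per trial (pinned header, see
  :data:`SESSION_COLUMNS`); booleans serialize as ``true``/``false``,
  missing values as empty fields, floats via ``repr`` so a
  write-read-write cycle is byte-identical;
* score tables and analysis summaries: CSV with fixed column order.

Writes are atomic (temp file + rename), and parse errors carry the
offending line number.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import os
import tempfile
from pathlib import Path

import pandas as pd
import yaml

from . import schedules as sch
from .cohort import SessionRecord
from .errors import ConfigError, SchemaError

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Atomic writes
# ---------------------------------------------------------------------------


def _atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# Trial schedules: JSON Lines
# ---------------------------------------------------------------------------


def write_trials(trials: list, task: str, path: str | Path) -> None:
    """Serialize one schedule to JSON Lines."""
    if task not in sch.TASKS:
        raise ValueError(f"unknown task {task!r}")
    lines = []
    for i, trial in enumerate(trials):
        condition = trial.condition
        lines.append(
            json.dumps(
                {"task": task, "trial_index": i, "condition": condition,
                 "payload": trial.to_payload()},
                separators=(",", ":"),
            )
        )
    _atomic_write_text(path, "\n".join(lines) + "\n")


def read_trials(path: str | Path) -> tuple[str, list]:
    """Parse a JSON Lines schedule back into trial objects."""
    trials = []
    task = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"invalid JSON: {exc.msg}", line=lineno) from None
            for key in ("task", "trial_index", "condition", "payload"):
                if key not in obj:
                    raise SchemaError(f"missing field {key!r}", line=lineno)
            if obj["task"] not in sch.TRIAL_TYPES:
                raise SchemaError(f"unknown task {obj['task']!r}", line=lineno)
            if task is None:
                task = obj["task"]
            elif obj["task"] != task:
                raise SchemaError(
                    f"mixed tasks in one schedule file ({task!r} vs {obj['task']!r})",
                    line=lineno,
                )
            try:
                trials.append(sch.TRIAL_TYPES[obj["task"]].from_payload(obj["payload"]))
            except (KeyError, TypeError, ValueError) as exc:
                raise SchemaError(f"malformed payload: {exc}", line=lineno) from None
    if task is None:
        raise SchemaError("empty schedule file", line=1)
    return task, trials


# ---------------------------------------------------------------------------
# Sessions: tidy CSV
# ---------------------------------------------------------------------------

SESSION_COLUMNS = [
    "participant_id", "day", "task", "trial_index", "condition",
    "is_practice", "correct", "n_correct", "n_targets", "rt_ms", "response",
    "task_type", "is_switch", "is_go", "responded", "is_repeat",
    "distance_class", "foveal_correct", "peripheral_correct", "length",
]

#: Which trial-dict keys each task's rows carry (everything else is empty).
TASK_TRIAL_KEYS = {
    "mot": ("trial_index", "condition", "n_correct", "n_targets", "correct"),
    "enumeration": ("trial_index", "condition", "correct", "response"),
    "lib": ("trial_index", "condition", "foveal_correct", "peripheral_correct", "correct"),
    "gonogo": ("trial_index", "condition", "is_go", "responded", "correct", "rt_ms"),
    "switch": ("trial_index", "condition", "task_type", "is_switch", "is_practice",
               "correct", "rt_ms"),
    "corsi": ("trial_index", "condition", "length", "correct"),
    "memorability": ("trial_index", "condition", "is_repeat", "distance_class",
                     "responded", "correct", "rt_ms"),
}

_BOOL_COLUMNS = {"is_practice", "correct", "is_switch", "is_go", "responded",
                 "is_repeat", "foveal_correct", "peripheral_correct"}
_INT_COLUMNS = {"day", "trial_index", "n_correct", "n_targets", "response", "length"}
_FLOAT_COLUMNS = {"rt_ms"}


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_cell(column: str, text: str, lineno: int):
    if text == "":
        return None
    try:
        if column in _BOOL_COLUMNS:
            if text not in ("true", "false"):
                raise ValueError(f"expected true/false, got {text!r}")
            return text == "true"
        if column in _INT_COLUMNS:
            return int(text)
        if column in _FLOAT_COLUMNS:
            return float(text)
        return text
    except ValueError as exc:
        raise SchemaError(f"column {column!r}: {exc}", line=lineno) from None


def write_sessions(records: list[SessionRecord], path: str | Path) -> None:
    """Write session records to the tidy CSV schema (atomic)."""
    import io

    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(SESSION_COLUMNS)
    for rec in records:
        if rec.task not in TASK_TRIAL_KEYS:
            raise ValueError(f"unknown task {rec.task!r}")
        for trial in rec.trials:
            row = {"participant_id": rec.participant_id, "day": rec.day, "task": rec.task}
            row.update({k: trial.get(k) for k in TASK_TRIAL_KEYS[rec.task]})
            writer.writerow([_cell(row.get(c)) for c in SESSION_COLUMNS])
    _atomic_write_text(path, buf.getvalue())


def read_sessions(path: str | Path) -> list[SessionRecord]:
    """Parse the tidy session CSV back into SessionRecords.

    Rows are grouped into one record per contiguous (participant, day,
    task) run; the write-read round trip is lossless.
    """
    records: list[SessionRecord] = []
    current_key = None
    current: SessionRecord | None = None
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty session file", line=1) from None
        if header != SESSION_COLUMNS:
            raise SchemaError(
                f"header mismatch: expected {SESSION_COLUMNS[:4]}..., got {header[:4]}...",
                line=1,
            )
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(SESSION_COLUMNS):
                raise SchemaError(
                    f"{len(row)} fields, expected {len(SESSION_COLUMNS)}", line=lineno
                )
            values = {c: _parse_cell(c, v, lineno) for c, v in zip(SESSION_COLUMNS, row)}
            task = values["task"]
            if task not in TASK_TRIAL_KEYS:
                raise SchemaError(f"unknown task {task!r}", line=lineno)
            if values["participant_id"] is None or values["day"] is None:
                raise SchemaError("missing participant_id or day", line=lineno)
            key = (values["participant_id"], values["day"], task)
            if key != current_key:
                current = SessionRecord(values["participant_id"], values["day"], task, [])
                records.append(current)
                current_key = key
            current.trials.append({k: values[k] for k in TASK_TRIAL_KEYS[task]})
    if not records:
        raise SchemaError("session file holds a header but no trials", line=2)
    return records


# ---------------------------------------------------------------------------
# Score tables and summaries
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ["participant_id", "day", "task", "condition", "metric", "value", "k", "n"]


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy score table with the pinned column order."""
    missing = [c for c in SCORE_COLUMNS if c not in scores.columns]
    if missing:
        raise ValueError(f"score table lacks columns {missing}")
    out = scores[SCORE_COLUMNS]
    _atomic_write_text(path, out.to_csv(index=False, lineterminator="\n"))


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != SCORE_COLUMNS:
        raise SchemaError(f"score table header mismatch: {list(df.columns)}", line=1)
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "tasks": {
        "mot": {"speeds": [1.0, 4.0, 8.0], "trials_per_speed": 10, "frame_rate": 60.0},
        "enumeration": {"set_sizes": [5, 6, 7, 8, 9], "trials_per_condition": 20},
        "lib": {"eccentricities": [3.0, 6.0], "trials_per_condition": 20},
        "gonogo": {"n_go": 18, "n_nogo": 18},
        "switch": {"n_per_task": 30, "n_practice": 20},
        "corsi": {"lengths": [4, 5, 6, 7, 8], "trials_per_length": 12},
        "memorability": {"categories": ["bedroom", "kitchen"], "catalog_size": 100},
    },
    "cohort": {"n_participants": 50},
    "analysis": {
        "draws": 10000,
        "k_components": 6,
        "rt_prior_upper": 1000.0,
        "seed": None,
    },
    "output": {"dir": "battery_out"},
}


def _merge_block(defaults: dict, overrides: dict, context: str) -> dict:
    merged = dict(defaults)
    for key, value in overrides.items():
        if key not in defaults and context in ("tasks", "analysis", "output"):
            raise ConfigError(f"unknown key {context}.{key}")
        if isinstance(merged.get(key), dict) and isinstance(value, dict):
            merged[key] = _merge_block(merged[key], value, f"{context}.{key}")
        else:
            merged[key] = value
    return merged


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML/JSON config document over the battery-standard defaults.

    Unknown keys are rejected; a missing analysis seed is auto-filled with
    0 and logged so every run has explicit seeds.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config document must be a mapping")
    if overrides:
        data = _merge_block(data, overrides, "overrides")
    for key in data:
        if key not in DEFAULT_CONFIG:
            raise ConfigError(f"unknown config key {key!r}")
    cfg = {
        block: _merge_block(DEFAULT_CONFIG[block], data.get(block, {}), block)
        for block in DEFAULT_CONFIG
    }
    if cfg["analysis"]["seed"] is None:
        cfg["analysis"]["seed"] = 0
        logger.info("analysis.seed not given; filled with 0")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config document, for run manifests."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
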