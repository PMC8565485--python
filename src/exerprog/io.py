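"""File formats: game catalogs, session logs and plan exports.

Session logs are plain CSV with a fixed header — small, human-auditable
clinical records.  Floats are written with Python's shortest round-trip
representation so write -> read -> write is byte-stable; missing
ratings (dropped sessions) are empty fields.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Sequence

import yaml

from .planner import SessionPlan
from .simulate import SessionRecord
from .taxonomy import GameSpec

__all__ = [
    "SESSION_LOG_COLUMNS",
    "SessionLogError",
    "read_session_log",
    "write_session_log",
    "load_catalog",
    "write_plan_json",
    "write_plan_csv",
]

SESSION_LOG_COLUMNS = [
    "participant_id",
    "session_index",
    "week",
    "group",
    "anchor_row",
    "anchor_col",
    "planned_min",
    "attended_min",
    "motor_vas",
    "cognitive_vas",
    "motivation",
    "satisfaction",
    "dropped",
]


class SessionLogError(ValueError):
    """A session-log file violates the schema; the message cites the row."""


def _fmt(value: float) -> str:
    if isinstance(value, float) and math.isnan(value):
        return ""
    return repr(value) if isinstance(value, float) else str(value)


def write_session_log(records: Sequence[SessionRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SESSION_LOG_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.participant_id,
                    r.session_index,
                    r.week,
                    r.group,
                    r.anchor_row,
                    r.anchor_col,
                    _fmt(r.planned_min),
                    _fmt(r.attended_min),
                    _fmt(r.motor_vas),
                    _fmt(r.cognitive_vas),
                    _fmt(r.motivation),
                    _fmt(r.satisfaction),
                    int(r.dropped),
                ]
            )


def _parse_float(value: str, name: str, row: int, lo: float, hi: float) -> float:
    if value == "":
        return math.nan
    try:
        x = float(value)
    except ValueError as exc:
        raise SessionLogError(f"row {row}: {name} is not a number: {value!r}") from exc
    if not (lo <= x <= hi):
        raise SessionLogError(f"row {row}: {name}={x} outside [{lo}, {hi}]")
    return x


def read_session_log(path: str | Path) -> list[SessionRecord]:
    """Read a session log, validating types, bounds and the exact header."""
    records: list[SessionRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != SESSION_LOG_COLUMNS:
            missing = set(SESSION_LOG_COLUMNS) - set(reader.fieldnames or [])
            raise SessionLogError(
                f"bad header: expected {SESSION_LOG_COLUMNS}, "
                f"missing {sorted(missing)}"
            )
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                dropped_raw = row["dropped"]
                if dropped_raw not in ("0", "1"):
                    raise SessionLogError(
                        f"row {i}: dropped must be 0 or 1, got {dropped_raw!r}"
                    )
                records.append(
                    SessionRecord(
                        participant_id=row["participant_id"],
                        session_index=int(row["session_index"]),
                        week=int(row["week"]),
                        group=row["group"],
                        anchor_row=int(row["anchor_row"]),
                        anchor_col=int(row["anchor_col"]),
                        planned_min=_parse_float(
                            row["planned_min"], "planned_min", i, 0.0, math.inf
                        ),
                        attended_min=_parse_float(
                            row["attended_min"], "attended_min", i, 0.0, math.inf
                        ),
                        motor_vas=_parse_float(row["motor_vas"], "motor_vas", i, 0, 9),
                        cognitive_vas=_parse_float(
                            row["cognitive_vas"], "cognitive_vas", i, 0, 9
                        ),
                        motivation=_parse_float(
                            row["motivation"], "motivation", i, 0, 10
                        ),
                        satisfaction=_parse_float(
                            row["satisfaction"], "satisfaction", i, 0, 10
                        ),
                        dropped=dropped_raw == "1",
                    )
                )
            except SessionLogError:
                raise
            except (KeyError, TypeError, ValueError) as exc:
                raise SessionLogError(f"row {i}: {exc}") from exc
    return records


def load_catalog(path: str | Path) -> list[GameSpec]:
    """Load a game catalog from a YAML or JSON list of records.

    Each record: {id, action, env, domain, min_block_s, max_block_s};
    the block bounds are optional (defaults 60/180 s).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, list):
        raise ValueError("catalog must be a list of game records")
    games = []
    for i, rec in enumerate(raw):
        if not isinstance(rec, dict) or "id" not in rec:
            raise ValueError(f"catalog entry {i} must be a mapping with an 'id'")
        games.append(
            GameSpec(
                game_id=str(rec["id"]),
                action=rec["action"],
                env=rec["env"],
                domain=rec["domain"],
                min_block_s=int(rec.get("min_block_s", 60)),
                max_block_s=int(rec.get("max_block_s", 180)),
            )
        )
    return games


def write_plan_json(plan: SessionPlan, path: str | Path) -> None:
    payload = {
        "session_index": plan.session_index,
        "week": plan.week,
        "group": plan.group.group.value,
        "baseline_tug_s": plan.group.baseline_tug_s,
        "anchor_row": plan.square.anchor_row,
        "anchor_col": plan.square.anchor_col,
        "scheduled_min": plan.scheduled_min,
        "blocks": plan.to_records(),
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def write_plan_csv(plan: SessionPlan, path: str | Path) -> None:
    cols = [
        "session_index",
        "phase",
        "cell_row",
        "cell_col",
        "game_id",
        "duration_s",
        "difficulty_rank",
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rec in plan.to_records():
            writer.writerow([rec[c] for c in cols])
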