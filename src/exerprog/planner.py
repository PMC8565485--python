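"""Dosing groups, weekly session durations and session composition.

Participants are stratified by their baseline Timed-up-and-go (TUG)
time: more than 10 s -> basic group, 10 s or less -> advanced group.
Both groups train twice per week for 8 weeks (16 planned sessions) and
gain 3 minutes of training per week: basic 15 -> 36 min, advanced
24 -> 45 min.

Each session consists of a 3-min warm-up, a main part and a 3-min
cool-down, all counted inside the scheduled minutes (so a 15-min
session has a 9-min main part; the main part spans 9-39 min across
groups and weeks).  Warm-up and cool-down games come from the position
square's top-left sub-category (its easiest content); the main part is
tiled with 60-180 s blocks drawn from the remaining three cells,
ordered by increasing difficulty so that perceived difficulty rises
after the warm-up and peaks in the last third of the main part.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .progression import PositionSquare
from .taxonomy import GameSpec, TaxonomyGrid, resolve_game

__all__ = [
    "TrainingGroup",
    "GroupAssignment",
    "ScheduleConfig",
    "DEFAULT_SCHEDULE",
    "GameBlock",
    "SessionPlan",
    "SessionTooShortError",
    "TUG_CUTOFF_S",
    "WEEKS",
    "SESSIONS_PER_WEEK",
    "N_SESSIONS",
    "assign_group",
    "session_minutes",
    "difficulty_rank",
    "plan_session",
]

TUG_CUTOFF_S = 10.0
WEEKS = 8
SESSIONS_PER_WEEK = 2
N_SESSIONS = WEEKS * SESSIONS_PER_WEEK

MIN_BLOCK_S = 60
MAX_BLOCK_S = 180


class SessionTooShortError(ValueError):
    """Scheduled minutes leave less than one minimal main block."""


class TrainingGroup(str, Enum):
    BASIC = "basic"
    ADVANCED = "advanced"

    @property
    def start_minutes(self) -> int:
        """Scheduled minutes in week 1 (basic 15, advanced 24)."""
        return 15 if self is TrainingGroup.BASIC else 24


@dataclass(frozen=True)
class GroupAssignment:
    """Dosing group together with the TUG time that determined it."""

    group: TrainingGroup
    baseline_tug_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", TrainingGroup(self.group))
        if not self.baseline_tug_s > 0:
            raise ValueError("baseline_tug_s must be positive")
        expected = (
            TrainingGroup.BASIC
            if self.baseline_tug_s > TUG_CUTOFF_S
            else TrainingGroup.ADVANCED
        )
        if self.group is not expected:
            raise ValueError(
                f"TUG {self.baseline_tug_s} s implies group {expected.value!r}, "
                f"got {self.group.value!r}"
            )


def assign_group(baseline_tug_s: float) -> GroupAssignment:
    """Stratify by TUG: > 10 s -> basic, <= 10 s -> advanced."""
    if not baseline_tug_s > 0:
        raise ValueError("baseline_tug_s must be positive")
    group = (
        TrainingGroup.BASIC
        if baseline_tug_s > TUG_CUTOFF_S
        else TrainingGroup.ADVANCED
    )
    return GroupAssignment(group=group, baseline_tug_s=baseline_tug_s)


def session_minutes(group: TrainingGroup | GroupAssignment | str, week: int) -> int:
    """Scheduled minutes for a week: start minutes + 3 per completed week."""
    if isinstance(group, GroupAssignment):
        group = group.group
    group = TrainingGroup(group)
    if not (1 <= week <= WEEKS):
        raise ValueError(f"week must lie in [1, {WEEKS}], got {week}")
    return group.start_minutes + 3 * (week - 1)


@dataclass(frozen=True)
class ScheduleConfig:
    """Calendar and block-composition parameters of the protocol."""

    sessions_per_week: int = SESSIONS_PER_WEEK
    weeks: int = WEEKS
    warmup_s: int = 180
    cooldown_s: int = 180
    quantum_s: int = 90

    def __post_init__(self) -> None:
        if self.sessions_per_week < 1 or self.weeks < 1:
            raise ValueError("sessions_per_week and weeks must be >= 1")
        if not (MIN_BLOCK_S <= self.quantum_s <= MAX_BLOCK_S):
            raise ValueError(
                f"quantum_s must lie in [{MIN_BLOCK_S}, {MAX_BLOCK_S}]"
            )
        if self.warmup_s <= 0 or self.cooldown_s <= 0:
            raise ValueError("warmup_s and cooldown_s must be positive")

    @property
    def n_sessions(self) -> int:
        return self.sessions_per_week * self.weeks


DEFAULT_SCHEDULE = ScheduleConfig()

# Rank order of the square's cells: (row_offset, col_offset) sorted by
# (row_offset + col_offset, row_offset).
_RANKED_OFFSETS = ((0, 0), (0, 1), (1, 0), (1, 1))


def difficulty_rank(square: PositionSquare, cell: tuple[int, int]) -> int:
    """Order the square's four cells by combined demand.

    top-left -> 0, top-right -> 1, bottom-left -> 2, bottom-right -> 3
    (diagonal ties broken in favour of the cognitive axis).
    """
    dr = cell[0] - square.anchor_row
    dc = cell[1] - square.anchor_col
    if (dr, dc) not in _RANKED_OFFSETS:
        raise ValueError(f"cell {cell} is not inside square anchored at {square.top_left}")
    return _RANKED_OFFSETS.index((dr, dc))


@dataclass(frozen=True)
class GameBlock:
    game: GameSpec
    cell: tuple[int, int]
    duration_s: int
    phase: str  # warmup | main | cooldown
    difficulty_rank: int


@dataclass(frozen=True)
class SessionPlan:
    """Ordered, timed game blocks for one training session."""

    week: int
    session_index: int
    group: GroupAssignment
    square: PositionSquare
    scheduled_min: int
    blocks: tuple[GameBlock, ...]

    @property
    def total_s(self) -> int:
        return sum(b.duration_s for b in self.blocks)

    @property
    def main_s(self) -> int:
        return sum(b.duration_s for b in self.blocks if b.phase == "main")

    def to_records(self) -> list[dict]:
        """One flat dict per block, suitable for CSV/JSON export."""
        return [
            {
                "session_index": self.session_index,
                "week": self.week,
                "group": self.group.group.value,
                "phase": b.phase,
                "cell_row": b.cell[0],
                "cell_col": b.cell[1],
                "game_id": b.game.game_id,
                "duration_s": b.duration_s,
                "difficulty_rank": b.difficulty_rank,
            }
            for b in self.blocks
        ]


def _near_equal(total: int, n: int) -> list[int]:
    base = total // n
    dur = [base] * n
    dur[-1] += total - base * n
    return dur


def _tile_main(main_s: int, quantum_s: int) -> list[int]:
    """Split the main part into block durations within [60, 180] s.

    Tiles with the quantum, the final block absorbing the remainder.
    If fewer than three blocks would result while the main part could
    hold three minimal blocks, a near-equal three-way split is used
    instead so every non-top-left cell can contribute a block.
    """
    if main_s < MIN_BLOCK_S:
        raise SessionTooShortError(
            f"main part of {main_s} s is shorter than one {MIN_BLOCK_S} s block"
        )
    n = main_s // quantum_s
    if n == 0:
        dur = [main_s] if main_s <= MAX_BLOCK_S else _near_equal(main_s, 2)
    else:
        rem = main_s - n * quantum_s
        dur = [quantum_s] * n
        if rem:
            if dur[-1] + rem <= MAX_BLOCK_S:
                dur[-1] += rem
            else:
                dur = _near_equal(main_s, n + 1)
    if main_s >= 3 * MIN_BLOCK_S and len(dur) < 3:
        dur = _near_equal(main_s, 3)
    assert sum(dur) == main_s and all(MIN_BLOCK_S <= d <= MAX_BLOCK_S for d in dur)
    return dur


def plan_session(
    square: PositionSquare,
    grid: TaxonomyGrid,
    group: GroupAssignment,
    week: int,
    session_index: int | None = None,
    schedule: ScheduleConfig = DEFAULT_SCHEDULE,
    policy: str = "deterministic",
    rng: np.random.Generator | None = None,
) -> SessionPlan:
    """Compose warm-up, ramped main part and cool-down for one session.

    The warm-up and cool-down are single blocks from the square's
    top-left cell.  Main blocks are drawn from the square's other three
    cells (empty cells fall back to the nearest non-empty one) and are
    ordered by non-decreasing difficulty rank; when at least three
    blocks fit, each of the three cells contributes at least one, with
    surplus blocks allotted to the easier cells so the hardest content
    lands in the final third.
    """
    minutes = session_minutes(group, week)
    if session_index is None:
        session_index = (week - 1) * schedule.sessions_per_week + 1
    main_s = minutes * 60 - schedule.warmup_s - schedule.cooldown_s
    durations = _tile_main(main_s, schedule.quantum_s)
    n = len(durations)

    # ranks 1..3 = top-right, bottom-left, bottom-right
    main_cells = {rank: square.cells[rank] for rank in (1, 2, 3)}
    if n >= 3:
        counts = {rank: n // 3 for rank in (1, 2, 3)}
        for rank in (1, 2)[: n % 3]:
            counts[rank] += 1
    else:
        counts = {rank: 0 for rank in (1, 2, 3)}
        for rank in (1, 2)[:n]:
            counts[rank] = 1
    rank_seq = [rank for rank in (1, 2, 3) for _ in range(counts[rank])]

    blocks: list[GameBlock] = []
    top_left = square.top_left
    warm = resolve_game(grid, *top_left, policy=policy, rng=rng)
    blocks.append(GameBlock(warm.game, warm.cell, schedule.warmup_s, "warmup", 0))
    for rank, dur in zip(rank_seq, durations):
        cell = main_cells[rank]
        res = resolve_game(grid, *cell, policy=policy, rng=rng)
        blocks.append(GameBlock(res.game, res.cell, dur, "main", rank))
    cool = resolve_game(grid, *top_left, policy=policy, rng=rng)
    blocks.append(GameBlock(cool.game, cool.cell, schedule.cooldown_s, "cooldown", 0))

    plan = SessionPlan(
        week=week,
        session_index=session_index,
        group=group,
        square=square,
        scheduled_min=minutes,
        blocks=tuple(blocks),
    )
    assert plan.total_s == minutes * 60
    return plan
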