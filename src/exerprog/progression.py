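"""Rating-zone classification and position-square progression.

After each training session the participant rates perceived motor and
cognitive task difficulty on a visual analog scale from 0 ("very very
easy") to 9 ("very very difficult").  Following Cognitive Load Theory
the protocol targets a band from "neither easy nor difficult" to
"difficult": a rating inside the band leaves the difficulty unchanged,
a rating below it triggers a soft (+1) or hard (+2) progression, a
rating above it a soft (-1) or hard (-2) regression.

The difficulty state is a "position square": a 2x2 window into the 12x3
taxonomy grid identified by its top-left anchor.  The motor rating moves
the square on the x-axis (columns), the cognitive rating on the y-axis
(rows); moves are clamped at the grid edges.

The default zone boundaries place the nine verbal anchors of the
difficulty scale evenly on [0, 9] (spacing 1.125):

===============  ==================  =====
zone             interval            move
===============  ==================  =====
hard progression [0, 2.25)           +2
soft progression [2.25, 4.5)         +1
target           [4.5, 6.75]          0
soft regression  (6.75, 7.875]       -1
hard regression  (7.875, 9]          -2
===============  ==================  =====
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "VAS_MAX",
    "MAX_ANCHOR_ROW",
    "MAX_ANCHOR_COL",
    "ZoneConfig",
    "DEFAULT_ZONES",
    "RatingPair",
    "PositionSquare",
    "classify_rating",
    "advance",
    "trajectory",
]

VAS_MAX = 9.0

# A 2x2 square must fit the 12x3 grid.
MAX_ANCHOR_ROW = 10
MAX_ANCHOR_COL = 1


@dataclass(frozen=True)
class ZoneConfig:
    """Boundaries partitioning the [0, 9] difficulty scale into five zones."""

    hard_up_max: float = 2.25
    soft_up_max: float = 4.5
    target_max: float = 6.75
    soft_down_max: float = 7.875

    def __post_init__(self) -> None:
        b = (self.hard_up_max, self.soft_up_max, self.target_max, self.soft_down_max)
        if not (0 < b[0] < b[1] < b[2] < b[3] < VAS_MAX):
            raise ValueError(
                f"zone boundaries must satisfy 0 < hard_up_max < soft_up_max "
                f"< target_max < soft_down_max < {VAS_MAX}, got {b}"
            )

    @property
    def target_center(self) -> float:
        """Midpoint of the target zone (5.625 under defaults)."""
        return 0.5 * (self.soft_up_max + self.target_max)

    def in_target(self, vas: float) -> bool:
        return self.soft_up_max <= vas <= self.target_max


DEFAULT_ZONES = ZoneConfig()


def _check_vas(vas: float, name: str = "vas") -> None:
    if not (0.0 <= vas <= VAS_MAX):
        raise ValueError(f"{name} must lie in [0, {VAS_MAX}], got {vas}")


@dataclass(frozen=True)
class RatingPair:
    """Post-session difficulty ratings: motor (x-axis) and cognitive (y-axis)."""

    motor_vas: float
    cognitive_vas: float

    def __post_init__(self) -> None:
        _check_vas(self.motor_vas, "motor_vas")
        _check_vas(self.cognitive_vas, "cognitive_vas")


@dataclass(frozen=True)
class PositionSquare:
    """A 2x2 window into the taxonomy grid, identified by its top-left anchor."""

    anchor_row: int
    anchor_col: int

    def __post_init__(self) -> None:
        if not (0 <= self.anchor_row <= MAX_ANCHOR_ROW):
            raise ValueError(f"anchor_row must lie in [0, {MAX_ANCHOR_ROW}]")
        if not (0 <= self.anchor_col <= MAX_ANCHOR_COL):
            raise ValueError(f"anchor_col must lie in [0, {MAX_ANCHOR_COL}]")

    @property
    def top_left(self) -> tuple[int, int]:
        return (self.anchor_row, self.anchor_col)

    @property
    def cells(self) -> tuple[tuple[int, int], ...]:
        """The four covered cells: top-left, top-right, bottom-left, bottom-right."""
        r, c = self.anchor_row, self.anchor_col
        return ((r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1))


def classify_rating(vas: float, zones: ZoneConfig = DEFAULT_ZONES) -> int:
    """Map a difficulty rating to a progression step.

    Returns +2/+1 for the hard/soft progression zones (task felt too
    easy), 0 in the target zone, -1/-2 for the soft/hard regression
    zones (task felt too hard).  The target zone is closed at both ends;
    the others are half-open as tabulated in the module docstring.
    """
    _check_vas(vas)
    if vas < zones.hard_up_max:
        return 2
    if vas < zones.soft_up_max:
        return 1
    if vas <= zones.target_max:
        return 0
    if vas <= zones.soft_down_max:
        return -1
    return -2


def advance(
    square: PositionSquare, ratings: RatingPair, zones: ZoneConfig = DEFAULT_ZONES
) -> PositionSquare:
    """Apply one session's ratings to the position square.

    The motor rating moves the anchor column, the cognitive rating the
    anchor row; both are clamped so the 2x2 square stays on the grid.
    A new square is returned; the input is left unmodified.
    """
    d_col = classify_rating(ratings.motor_vas, zones)
    d_row = classify_rating(ratings.cognitive_vas, zones)
    return PositionSquare(
        anchor_row=min(max(square.anchor_row + d_row, 0), MAX_ANCHOR_ROW),
        anchor_col=min(max(square.anchor_col + d_col, 0), MAX_ANCHOR_COL),
    )


def trajectory(
    initial: PositionSquare,
    rating_sequence: Iterable[RatingPair],
    zones: ZoneConfig = DEFAULT_ZONES,
) -> list[PositionSquare]:
    """Fold :func:`advance` over a rating sequence; includes the start square."""
    path = [initial]
    for ratings in rating_sequence:
        path.append(advance(path[-1], ratings, zones))
    return path
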