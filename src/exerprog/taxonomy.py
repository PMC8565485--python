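"""Adapted Gentile taxonomy of motor-cognitive skill sub-categories.

Gentile's taxonomy classifies motor skills along two dimensions:
environmental context and action function.  The adaptation implemented
here keeps three ordered levels on each motor axis — environmental
inter-trial variability and action function — giving 9 motor skill
categories, and splits each of them into four cognitive domains
(attention, executive, memory, visuo-spatial).  The result is a grid of
36 skill sub-categories, each holding the exergames that train it.

Canonical in-memory layout
--------------------------
A 12 x 3 grid.  Columns are the action-function levels (the motor
x-axis).  Rows interleave environmental variability (major, three
blocks of four) with the cognitive domain (minor, fixed canonical order
attention -> executive -> memory -> visuospatial), so the row index is a
single ordered cognitive/environmental difficulty axis::

    row = 4 * env_index + domain_offset        # 0..11
    col = action_index                         # 0..2

Cells may be empty — a real game catalog does not cover every
sub-category (memory games in particular tend to be missing).  Empty
cells are served at planning time by the nearest non-empty neighbour,
see :func:`resolve_game`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ActionLevel",
    "EnvLevel",
    "CognitiveDomain",
    "GameSpec",
    "TaxonomyGrid",
    "CoverageSummary",
    "ResolvedGame",
    "CatalogError",
    "EmptyGridError",
    "N_ROWS",
    "N_COLS",
    "N_CELLS",
    "coords_of",
    "triple_at",
    "build_grid",
    "resolve_game",
    "demo_catalog",
]

N_ROWS = 12
N_COLS = 3
N_CELLS = N_ROWS * N_COLS


class CatalogError(ValueError):
    """Raised when a game catalog violates its invariants."""


class EmptyGridError(LookupError):
    """Raised when game resolution is requested on a grid with no games."""


class ActionLevel(str, Enum):
    """Action-function level: how much the centre of pressure must travel.

    Ordered from stable limits of stability (body stability) through
    moderately changing (partial body transport) to constantly and
    rapidly changing limits (body transport).
    """

    BODY_STABILITY = "body_stability"
    PARTIAL_BODY_TRANSPORT = "partial_body_transport"
    BODY_TRANSPORT = "body_transport"

    @property
    def index(self) -> int:
        """Column index, 0 (easiest) .. 2 (hardest)."""
        return _ACTION_INDEX[self]


class EnvLevel(str, Enum):
    """Environmental context: amount of inter-trial variability."""

    NO_VARIABILITY = "no_variability"
    PARTIAL_VARIABILITY = "partial_variability"
    FULL_VARIABILITY = "full_variability"

    @property
    def index(self) -> int:
        """Row-block index, 0 (easiest) .. 2 (hardest)."""
        return _ENV_INDEX[self]


class CognitiveDomain(str, Enum):
    """Cognitive domain targeted by a game, in canonical order."""

    ATTENTION = "attention"
    EXECUTIVE = "executive"
    MEMORY = "memory"
    VISUOSPATIAL = "visuospatial"

    @property
    def offset(self) -> int:
        """Within-block row offset, 0..3."""
        return _DOMAIN_OFFSET[self]


_ACTION_INDEX = {m: i for i, m in enumerate(ActionLevel)}
_ENV_INDEX = {m: i for i, m in enumerate(EnvLevel)}
_DOMAIN_OFFSET = {m: i for i, m in enumerate(CognitiveDomain)}


def coords_of(
    env: EnvLevel | str, domain: CognitiveDomain | str, action: ActionLevel | str
) -> tuple[int, int]:
    """Map an (environment, cognitive domain, action) triple to its grid cell.

    The mapping is a bijection between the 36 level triples and the 36
    (row, col) addresses: ``row = 4*env_index + domain_offset``,
    ``col = action_index``.
    """
    env = EnvLevel(env)
    domain = CognitiveDomain(domain)
    action = ActionLevel(action)
    return 4 * env.index + domain.offset, action.index


def triple_at(row: int, col: int) -> tuple[EnvLevel, CognitiveDomain, ActionLevel]:
    """Inverse of :func:`coords_of`."""
    _check_cell(row, col)
    return (
        list(EnvLevel)[row // 4],
        list(CognitiveDomain)[row % 4],
        list(ActionLevel)[col],
    )


def _check_cell(row: int, col: int) -> None:
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise IndexError(f"cell ({row},{col}) outside the {N_ROWS}x{N_COLS} grid")


@dataclass(frozen=True)
class GameSpec:
    """A single exergame and the sub-category it trains.

    ``min_block_s``/``max_block_s`` bound how long one block of this game
    may run inside a session (defaults 60–180 s).
    """

    game_id: str
    action: ActionLevel
    env: EnvLevel
    domain: CognitiveDomain
    min_block_s: int = 60
    max_block_s: int = 180

    def __post_init__(self) -> None:
        if not self.game_id:
            raise CatalogError("game_id must be a non-empty string")
        object.__setattr__(self, "action", ActionLevel(self.action))
        object.__setattr__(self, "env", EnvLevel(self.env))
        object.__setattr__(self, "domain", CognitiveDomain(self.domain))
        if not (0 < self.min_block_s <= self.max_block_s):
            raise CatalogError(
                f"game {self.game_id!r}: require 0 < min_block_s <= max_block_s, "
                f"got ({self.min_block_s}, {self.max_block_s})"
            )

    @property
    def cell(self) -> tuple[int, int]:
        """The (row, col) grid address of this game's sub-category."""
        return coords_of(self.env, self.domain, self.action)


@dataclass(frozen=True)
class CoverageSummary:
    """Which of the 36 sub-categories have at least one game."""

    n_cells: int
    n_filled: int
    n_games: int
    empty_cells: tuple[tuple[int, int], ...]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.n_filled}/{self.n_cells} sub-categories covered "
            f"by {self.n_games} games; empty: {list(self.empty_cells)}"
        )


@dataclass(frozen=True)
class TaxonomyGrid:
    """The 12x3 grid of skill sub-categories with their candidate games."""

    cells: Mapping[tuple[int, int], tuple[GameSpec, ...]]

    def cell(self, row: int, col: int) -> tuple[GameSpec, ...]:
        _check_cell(row, col)
        return self.cells.get((row, col), ())

    def non_empty(self) -> list[tuple[int, int]]:
        """Addresses of all cells holding at least one game, row-major."""
        return sorted(rc for rc, games in self.cells.items() if games)

    def coverage(self) -> CoverageSummary:
        filled = self.non_empty()
        empty = tuple(
            (r, c)
            for r in range(N_ROWS)
            for c in range(N_COLS)
            if (r, c) not in set(filled)
        )
        n_games = sum(len(g) for g in self.cells.values())
        return CoverageSummary(N_CELLS, len(filled), n_games, empty)


def build_grid(catalog: Sequence[GameSpec]) -> TaxonomyGrid:
    """Place every catalog game into its sub-category cell.

    Duplicate game ids are rejected (not deduplicated) so that block
    provenance stays unambiguous.
    """
    seen: dict[str, GameSpec] = {}
    dupes: list[str] = []
    for g in catalog:
        if g.game_id in seen:
            dupes.append(g.game_id)
        seen[g.game_id] = g
    if dupes:
        raise CatalogError(f"duplicate game_id(s): {sorted(set(dupes))}")
    cells: dict[tuple[int, int], list[GameSpec]] = {
        (r, c): [] for r in range(N_ROWS) for c in range(N_COLS)
    }
    for g in catalog:
        cells[g.cell].append(g)
    return TaxonomyGrid({rc: tuple(gs) for rc, gs in cells.items()})


@dataclass(frozen=True)
class ResolvedGame:
    """A resolved game plus the cell it was actually drawn from."""

    game: GameSpec
    cell: tuple[int, int]


def resolve_game(
    grid: TaxonomyGrid,
    row: int,
    col: int,
    policy: str = "deterministic",
    rng: np.random.Generator | None = None,
) -> ResolvedGame:
    """Return a game for a sub-category, substituting from a neighbour if empty.

    A non-empty cell serves itself.  An empty cell is served by the
    non-empty cell at minimal Chebyshev distance; ties are broken by the
    lexicographically smallest (distance, row, col), which biases the
    donor toward lower (easier) indices.  Under ``policy="deterministic"``
    the first game by id is returned; under ``policy="random"`` a uniform
    draw from the donor cell is made with the supplied generator.
    """
    _check_cell(row, col)
    games = grid.cell(row, col)
    if games:
        donor = (row, col)
    else:
        candidates = grid.non_empty()
        if not candidates:
            raise EmptyGridError("cannot resolve a game: every grid cell is empty")
        donor = min(
            candidates,
            key=lambda rc: (max(abs(rc[0] - row), abs(rc[1] - col)), rc[0], rc[1]),
        )
        games = grid.cell(*donor)
    ordered = sorted(games, key=lambda g: g.game_id)
    if policy == "deterministic":
        game = ordered[0]
    elif policy == "random":
        if rng is None:
            raise ValueError('policy "random" requires an rng')
        game = ordered[int(rng.integers(len(ordered)))]
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return ResolvedGame(game, donor)


def demo_catalog(
    games_per_cell: int = 2,
    include_memory: bool = True,
    min_block_s: int = 60,
    max_block_s: int = 180,
) -> list[GameSpec]:
    """Synthetic demonstration catalog covering the grid programmatically.

    Generates ``games_per_cell`` games for every sub-category (optionally
    skipping the memory domain, the gap observed with real exergame
    libraries).  Ids encode the cell, e.g. ``g-e0-d2-a1-01``.
    """
    catalog: list[GameSpec] = []
    for env in EnvLevel:
        for domain in CognitiveDomain:
            if domain is CognitiveDomain.MEMORY and not include_memory:
                continue
            for action in ActionLevel:
                for k in range(games_per_cell):
                    catalog.append(
                        GameSpec(
                            game_id=f"g-e{env.index}-d{domain.offset}-a{action.index}-{k:02d}",
                            action=action,
                            env=env,
                            domain=domain,
                            min_block_s=min_block_s,
                            max_block_s=max_block_s,
                        )
                    )
    return catalog
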