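"""Simulated participants and full 8-week adaptive-training trials.

No participant-level data from adaptive exergame feasibility trials are
publicly available, so this module provides a synthetic cohort model
that exercises the whole progression/planning/analysis stack.

Each simulated patient carries a latent motor skill (on the column-
demand scale, [0, 2]) and a latent cognitive skill (row scale, [0, 11]).
The perceived difficulty of a session is a linear function of the
mismatch between the session's demand (the centre of the position
square on each axis) and the patient's skill, plus additive Gaussian
rating noise, clamped to the [0, 9] scale:

    vas = clamp(target_center + gain * (demand - skill) + eps, 0, 9)

A perfectly matched task is therefore rated at the centre of the target
zone.  Optional learning drift raises the skills by a fixed amount per
attended session, and an absorbing per-session dropout hazard produces
attrition: a dropped patient's remaining sessions stay offered but are
not attended, matching how feasibility bookkeeping counts them.

All randomness flows through one trial seed; each patient draws from a
substream keyed by a stable hash of the participant id, so adding or
removing patients does not reshuffle the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .planner import GroupAssignment, assign_group, session_minutes
from .progression import (
    DEFAULT_ZONES,
    PositionSquare,
    RatingPair,
    ZoneConfig,
    advance,
)

__all__ = [
    "MOTOR_SKILL_MAX",
    "COG_SKILL_MAX",
    "PatientParams",
    "PatientSamplerSpec",
    "TrialConfig",
    "SessionRecord",
    "SimulatedTrial",
    "demand_of",
    "perceived_rating",
    "update_skill",
    "sample_patients",
    "simulate_trial",
]

MOTOR_SKILL_MAX = 2.0
COG_SKILL_MAX = 11.0


@dataclass(frozen=True)
class PatientParams:
    """Latent parameters of one simulated participant."""

    participant_id: str
    motor_skill: float
    cog_skill: float
    gain: float = 1.0
    noise_sd: float = 1.0
    learning_rate: float = 0.05
    dropout_p: float = 0.016
    motivation_mean: float = 7.67
    satisfaction_mean: float = 7.44
    noise_sd_ms: float = 1.2
    baseline_tug_s: float | None = None

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ValueError("participant_id must be non-empty")
        if not (0.0 <= self.motor_skill <= MOTOR_SKILL_MAX):
            raise ValueError(f"motor_skill must lie in [0, {MOTOR_SKILL_MAX}]")
        if not (0.0 <= self.cog_skill <= COG_SKILL_MAX):
            raise ValueError(f"cog_skill must lie in [0, {COG_SKILL_MAX}]")
        if not self.gain > 0:
            raise ValueError("gain must be positive")
        if self.noise_sd < 0 or self.noise_sd_ms < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must lie in [0, 1)")
        for name in ("motivation_mean", "satisfaction_mean"):
            if not (0.0 <= getattr(self, name) <= 10.0):
                raise ValueError(f"{name} must lie in [0, 10]")
        if self.baseline_tug_s is not None and not self.baseline_tug_s > 0:
            raise ValueError("baseline_tug_s must be positive")


@dataclass(frozen=True)
class PatientSamplerSpec:
    """Population the synthetic cohort is drawn from.

    Skills are uniform over (a sub-range of) the demand scale; the TUG
    is lognormal around the published cohort median (8.24 s) with a
    log-sd that yields roughly 30% basic-group assignments.
    """

    motor_skill_range: tuple[float, float] = (0.2, 1.8)
    cog_skill_range: tuple[float, float] = (0.5, 9.5)
    gain: float = 1.0
    noise_sd: float = 1.0
    learning_rate: float = 0.05
    dropout_p: float = 0.016
    motivation_mean: float = 7.67
    satisfaction_mean: float = 7.44
    noise_sd_ms: float = 1.2
    tug_log_mean: float = math.log(8.24)
    tug_log_sd: float = 0.35


@dataclass(frozen=True)
class TrialConfig:
    """Study-level settings of a simulated trial."""

    zones: ZoneConfig = DEFAULT_ZONES
    initial_square: PositionSquare = PositionSquare(0, 0)
    sessions_per_week: int = 2
    weeks: int = 8
    n_screened: int = 23

    @property
    def n_sessions(self) -> int:
        return self.sessions_per_week * self.weeks


@dataclass(frozen=True)
class SessionRecord:
    """One offered session of one participant."""

    participant_id: str
    session_index: int
    week: int
    group: str
    anchor_row: int
    anchor_col: int
    planned_min: float
    attended_min: float
    motor_vas: float
    cognitive_vas: float
    motivation: float
    satisfaction: float
    dropped: bool

    def __post_init__(self) -> None:
        if self.attended_min > self.planned_min:
            raise ValueError("attended_min cannot exceed planned_min")


@dataclass(frozen=True)
class SimulatedTrial:
    records: tuple[SessionRecord, ...]
    screened: int
    included: int
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def demand_of(square: PositionSquare) -> tuple[float, float]:
    """Demand coordinate of a square: its centre on each axis.

    Returns (motor_demand, cognitive_demand) = (col + 0.5, row + 0.5).
    """
    return (square.anchor_col + 0.5, square.anchor_row + 0.5)


def perceived_rating(
    skill: float,
    demand: float,
    gain: float,
    noise_sd: float,
    rng: np.random.Generator,
    zones: ZoneConfig = DEFAULT_ZONES,
) -> float:
    """Linear mismatch model of perceived task difficulty on the 0-9 scale."""
    if not gain > 0:
        raise ValueError("gain must be positive")
    eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    vas = zones.target_center + gain * (demand - skill) + eps
    return float(min(max(vas, 0.0), 9.0))


def update_skill(params: PatientParams, session: SessionRecord) -> PatientParams:
    """Learning drift: skills rise by learning_rate per attended session."""
    if session.dropped or params.learning_rate == 0:
        return params
    return replace(
        params,
        motor_skill=min(params.motor_skill + params.learning_rate, MOTOR_SKILL_MAX),
        cog_skill=min(params.cog_skill + params.learning_rate, COG_SKILL_MAX),
    )


def _patient_rng(seed: int, participant_id: str) -> np.random.Generator:
    # stable across runs and patient-list composition
    return np.random.default_rng([seed, zlib.crc32(participant_id.encode("utf-8"))])


def _clamp01_10(x: float) -> float:
    return float(min(max(x, 0.0), 10.0))


def _simulate_patient(
    params: PatientParams, config: TrialConfig, seed: int
) -> list[SessionRecord]:
    rng = _patient_rng(seed, params.participant_id)
    tug = params.baseline_tug_s
    if tug is None:
        tug = float(rng.lognormal(math.log(8.24), 0.35))
    assignment: GroupAssignment = assign_group(tug)
    square = config.initial_square
    state = params
    dropped = False
    records: list[SessionRecord] = []
    for s in range(1, config.n_sessions + 1):
        week = (s - 1) // config.sessions_per_week + 1
        planned = session_minutes(assignment, week)
        if not dropped and state.dropout_p > 0 and rng.random() < state.dropout_p:
            dropped = True
        if dropped:
            records.append(
                SessionRecord(
                    participant_id=params.participant_id,
                    session_index=s,
                    week=week,
                    group=assignment.group.value,
                    anchor_row=square.anchor_row,
                    anchor_col=square.anchor_col,
                    planned_min=float(planned),
                    attended_min=0.0,
                    motor_vas=math.nan,
                    cognitive_vas=math.nan,
                    motivation=math.nan,
                    satisfaction=math.nan,
                    dropped=True,
                )
            )
            continue
        motor_demand, cog_demand = demand_of(square)
        motor_vas = perceived_rating(
            state.motor_skill, motor_demand, state.gain, state.noise_sd, rng, config.zones
        )
        cog_vas = perceived_rating(
            state.cog_skill, cog_demand, state.gain, state.noise_sd, rng, config.zones
        )
        motivation = _clamp01_10(rng.normal(state.motivation_mean, state.noise_sd_ms))
        satisfaction = _clamp01_10(rng.normal(state.satisfaction_mean, state.noise_sd_ms))
        record = SessionRecord(
            participant_id=params.participant_id,
            session_index=s,
            week=week,
            group=assignment.group.value,
            anchor_row=square.anchor_row,
            anchor_col=square.anchor_col,
            planned_min=float(planned),
            attended_min=float(planned),
            motor_vas=motor_vas,
            cognitive_vas=cog_vas,
            motivation=motivation,
            satisfaction=satisfaction,
            dropped=False,
        )
        records.append(record)
        square = advance(square, RatingPair(motor_vas, cog_vas), config.zones)
        state = update_skill(state, record)
    return records


def sample_patients(
    n: int,
    seed: int,
    spec: PatientSamplerSpec | None = None,
) -> list[PatientParams]:
    """Draw a synthetic cohort of ``n`` patients from the population spec."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or PatientSamplerSpec()
    rng = np.random.default_rng([seed, zlib.crc32(b"cohort-sampler")])
    patients = []
    for i in range(1, n + 1):
        pid = f"P{i:02d}"
        patients.append(
            PatientParams(
                participant_id=pid,
                motor_skill=float(rng.uniform(*spec.motor_skill_range)),
                cog_skill=float(rng.uniform(*spec.cog_skill_range)),
                gain=spec.gain,
                noise_sd=spec.noise_sd,
                learning_rate=spec.learning_rate,
                dropout_p=spec.dropout_p,
                motivation_mean=spec.motivation_mean,
                satisfaction_mean=spec.satisfaction_mean,
                noise_sd_ms=spec.noise_sd_ms,
                baseline_tug_s=float(
                    np.exp(rng.normal(spec.tug_log_mean, spec.tug_log_sd))
                ),
            )
        )
    return patients


def simulate_trial(
    patient_list: Sequence[PatientParams],
    config: TrialConfig | None = None,
    seed: int = 0,
) -> SimulatedTrial:
    """Run the full study loop (rate -> classify -> advance) for a cohort.

    Identical (patients, config, seed) inputs give identical trials.
    """
    if not patient_list:
        raise ValueError("patient_list must contain at least one patient")
    ids = [p.participant_id for p in patient_list]
    if len(set(ids)) != len(ids):
        raise ValueError("participant ids must be unique")
    config = config or TrialConfig()
    records: list[SessionRecord] = []
    for params in patient_list:
        records.extend(_simulate_patient(params, config, seed))
    return SimulatedTrial(
        records=tuple(records),
        screened=config.n_screened,
        included=len(patient_list),
        seed=seed,
    )
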