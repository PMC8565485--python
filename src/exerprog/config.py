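"""Run configuration: strict YAML/JSON loading with validated defaults.

A run config binds together the game catalog, the rating-zone
boundaries, the calendar/block schedule, the simulation settings and
the feasibility thresholds.  Unknown keys are rejected (listing every
offending key) so that a misspelled zone boundary cannot silently fall
back to a default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .analysis import FeasibilityThresholds
from .planner import ScheduleConfig
from .progression import ZoneConfig
from .simulate import PatientSamplerSpec

__all__ = ["ConfigError", "SimulationSettings", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """The configuration file violates the schema."""


@dataclass(frozen=True)
class SimulationSettings:
    """Cohort size and sampling settings for simulated trials.

    Defaults mirror the scale of a single-site feasibility study:
    23 screened, 13 included.
    """

    n_screened: int = 23
    n_included: int = 13
    seed: int = 0
    patients: PatientSamplerSpec = field(default_factory=PatientSamplerSpec)

    def __post_init__(self) -> None:
        if self.n_included < 1:
            raise ConfigError("n_included must be >= 1")
        if self.n_screened < self.n_included:
            raise ConfigError("n_screened must be >= n_included")


@dataclass(frozen=True)
class RunConfig:
    catalog_path: Path | None = None
    zones: ZoneConfig = field(default_factory=ZoneConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    thresholds: FeasibilityThresholds = field(default_factory=FeasibilityThresholds)


_SECTIONS = {
    "zones": ZoneConfig,
    "schedule": ScheduleConfig,
    "simulation": SimulationSettings,
    "thresholds": FeasibilityThresholds,
}


def _build_section(cls: type, data: Any, prefix: str, bad_keys: list[str]) -> Any:
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"section {prefix!r} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            bad_keys.append(f"{prefix}.{key}" if prefix else key)
            continue
        if key == "patients":
            value = _build_section(
                PatientSamplerSpec, value, f"{prefix}.patients", bad_keys
            )
        elif key in ("motor_skill_range", "cog_skill_range") and isinstance(
            value, list
        ):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Missing sections fall back to documented defaults; unknown keys
    anywhere in the file raise a :class:`ConfigError` naming all of
    them at once.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("top-level config must be a mapping")

    bad_keys: list[str] = []
    known_top = set(_SECTIONS) | {"catalog_path"}
    sections: dict[str, Any] = {}
    for key in raw:
        if key not in known_top:
            bad_keys.append(key)
    for name, cls in _SECTIONS.items():
        try:
            sections[name] = _build_section(cls, raw.get(name), name, bad_keys)
        except ConfigError:
            raise
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid section {name!r}: {exc}") from exc
    if bad_keys:
        raise ConfigError(f"unknown config key(s): {sorted(bad_keys)}")

    catalog_path = raw.get("catalog_path")
    if catalog_path is not None:
        catalog_path = Path(catalog_path)
        if not catalog_path.is_absolute():
            catalog_path = path.parent / catalog_path
        if not catalog_path.exists():
            raise ConfigError(f"catalog file not found: {catalog_path}")

    return RunConfig(catalog_path=catalog_path, **sections)
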