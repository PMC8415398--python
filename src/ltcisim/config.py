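"""Run configuration, validation, and CSV serialization.

A run is described by a JSON or YAML file with four optional blocks:

.. code-block:: yaml

    parameters:            # ModelParameters overrides (base-year defaults fill the rest)
      r_ind: 0.0008
    battery: test2         # a built-in scenario battery, or
    scenarios:             # explicit scenarios
      - name: high-reimb
        overrides: {reimb: 0.9}
    sensitivity:
      n: 200
      seed: 2019
      ranges: {r_ind: [0.0006, 0.001]}
    units: millions        # yuan | millions (CSV output scale)

Unknown keys are rejected; lever values outside the published scenario
ranges load with an extrapolation warning.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .params import ModelParameters
from .scenarios import (
    BATTERY_NAMES,
    LEVER_RANGES,
    LEVERS,
    Scenario,
    ScenarioResult,
    battery,
)
from .sensitivity import DEFAULT_RANGES, DEFAULT_SEED, SensitivityRange

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "results_to_frame",
    "write_trajectory_csv",
]

logger = logging.getLogger("ltcisim")

_PARAM_FIELDS = set(ModelParameters.__dataclass_fields__)


class ConfigError(ValueError):
    """A run configuration failed validation."""


class ScenarioSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    overrides: dict[str, float] = {}

    @field_validator("overrides")
    @classmethod
    def _known_levers(cls, v: dict[str, float]) -> dict[str, float]:
        for k in v:
            if k not in LEVERS:
                raise ValueError(f"unknown lever {k!r}; recognised: {LEVERS}")
        return v


class SensitivitySpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = 200
    seed: int = DEFAULT_SEED
    ranges: dict[str, tuple[float, float]] = {}

    @field_validator("ranges")
    @classmethod
    def _known_levers(cls, v):
        for k in v:
            if k not in LEVERS:
                raise ValueError(f"unknown lever {k!r}; recognised: {LEVERS}")
        return v


class RunConfig(BaseModel):
    """Validated run configuration; defaults fill every omitted value."""

    model_config = ConfigDict(extra="forbid")

    parameters: dict[str, float | int] = {}
    battery: Literal["test1", "test2", "test3", "test4", "all"] | None = None
    scenarios: list[ScenarioSpec] = []
    sensitivity: SensitivitySpec = SensitivitySpec()
    units: Literal["yuan", "millions"] = "yuan"

    @field_validator("parameters")
    @classmethod
    def _known_parameters(cls, v):
        for k in v:
            if k not in _PARAM_FIELDS:
                raise ValueError(
                    f"unknown model parameter {k!r}; "
                    f"valid names: {sorted(_PARAM_FIELDS)}"
                )
        return v

    def resolve_parameters(self) -> ModelParameters:
        """Base-year defaults with the configured overrides applied."""
        try:
            return ModelParameters(**self.parameters)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def resolve_scenarios(self) -> list[Scenario]:
        """The configured battery and/or explicit scenarios, in order."""
        out: list[Scenario] = []
        if self.battery == "all":
            for name in BATTERY_NAMES:
                out.extend(battery(name))
        elif self.battery:
            out.extend(battery(self.battery))
        out.extend(Scenario(s.name, dict(s.overrides)) for s in self.scenarios)
        for s in out:
            if s.is_extrapolation():
                logger.warning(
                    "scenario %s leaves the published lever ranges "
                    "(extrapolation)", s.name,
                )
        return out

    def resolve_ranges(self) -> tuple[SensitivityRange, ...]:
        """Sensitivity ranges: configured ones override the published defaults."""
        merged = {r.lever: r for r in DEFAULT_RANGES}
        for lever, (low, high) in self.sensitivity.ranges.items():
            merged[lever] = SensitivityRange(lever, low, high)
        return tuple(merged.values())


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a JSON/YAML run configuration.

    ``None`` or an empty file yields the all-defaults configuration.
    Validation failures raise :class:`ConfigError` naming the offending key.
    """
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file {path} is not valid YAML/JSON: {exc}") from exc
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    try:
        cfg = RunConfig(**raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigError(f"invalid config key {loc!r}: {first['msg']}") from exc
    # cross-field invariants not expressible per key
    cfg.resolve_parameters()
    return cfg


def results_to_frame(
    results: list[ScenarioResult], units: str = "yuan"
) -> pd.DataFrame:
    """Tidy table: one row per scenario × year, flows in ``units``."""
    if not results:
        raise ValueError("no scenario results to serialize")
    scale = {"yuan": 1.0, "millions": 1e-6}[units]
    rows = []
    for res in results:
        for rec in res.trajectory:
            rows.append(
                {
                    "scenario": res.name,
                    "year": rec.year,
                    "rev_individual": rec.rev_individual * scale,
                    "rev_enterprise": rec.rev_enterprise * scale,
                    "rev_government": rec.rev_government * scale,
                    "rev_total": rec.rev_total * scale,
                    "expenditure": rec.expenditure * scale,
                    "balance_annual": rec.balance_annual * scale,
                    "balance_cumulative": rec.balance_cumulative * scale,
                }
            )
    return pd.DataFrame(rows)


def write_trajectory_csv(
    results: list[ScenarioResult], path: str | Path, units: str = "yuan"
) -> Path:
    """Write scenario trajectories as tidy CSV at full double precision."""
    path = Path(path)
    frame = results_to_frame(results, units)
    frame.to_csv(path, index=False, float_format="%.17g")
    return path
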