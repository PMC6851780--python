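"""Run configuration: schema, defaults, YAML/JSON loading, validation.

An empty config file yields the full default parameter set (height 173 cm,
age 59 yr, CVt 3%, CVm 6%, RC 0.15 L/sec, 3–8 maneuvers, 20,902 tests).
Unknown keys are rejected by name, at any nesting level.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

import yaml

from .protocol import NonRepeatablePolicy, ProtocolConfig, StopRule
from .reference import RoundingMode, SubjectProfile, VariabilityModel, derive_sigmas
from .simulator import SimulationConfig

__all__ = ["RunConfig", "load_config"]


class ConfigError(ValueError):
    """A configuration file violates the schema."""


@dataclass(frozen=True)
class SubjectSection:
    height: float = 173.0
    age: float = 59.0
    population_sd: float = 0.51


@dataclass(frozen=True)
class VariabilitySection:
    cv_t: float = 0.03
    cv_m: float = 0.06
    rounding_mode: str = "rounded_2dp"


@dataclass(frozen=True)
class ProtocolSection:
    rc: Optional[float] = 0.15
    rc_grid: Optional[tuple[float, ...]] = None
    min_maneuvers: int = 3
    max_maneuvers: int = 8
    stop_rule: str = "early_stop"  # early_stop | fixed_stop | no_stop
    fixed_stop_k: Optional[int] = None
    nonrepeatable_policy: str = "discard"


@dataclass(frozen=True)
class SimulationSection:
    n_tests: int = 20_902
    seed: Optional[int] = None


@dataclass(frozen=True)
class OutputSection:
    directory: str = "."
    formats: tuple[str, ...] = ("csv", "json")


_SECTIONS = {
    "subject": SubjectSection,
    "variability": VariabilitySection,
    "protocol": ProtocolSection,
    "simulation": SimulationSection,
    "output": OutputSection,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a simulation or replication run."""

    subject: SubjectSection = field(default_factory=SubjectSection)
    variability: VariabilitySection = field(default_factory=VariabilitySection)
    protocol: ProtocolSection = field(default_factory=ProtocolSection)
    simulation: SimulationSection = field(default_factory=SimulationSection)
    output: OutputSection = field(default_factory=OutputSection)

    def __post_init__(self) -> None:
        # building the domain objects runs every component invariant
        self.subject_profile()
        self.variability_model()
        if self.protocol.rc is not None:
            self.protocol_config()
        elif not self.protocol.rc_grid:
            raise ConfigError("protocol: one of 'rc' or 'rc_grid' is required")
        for rc in self.rc_values():
            if not rc > 0:
                raise ConfigError(f"protocol.rc_grid: rc values must be positive, got {rc!r}")
        if self.simulation.n_tests < 1:
            raise ConfigError(f"simulation.n_tests must be >= 1, got {self.simulation.n_tests}")

    # -- domain object builders -------------------------------------------

    def subject_profile(self) -> SubjectProfile:
        try:
            return SubjectProfile(
                height_cm=self.subject.height,
                age_yr=self.subject.age,
                population_sd=self.subject.population_sd,
            )
        except ValueError as exc:
            raise ConfigError(f"subject: {exc}") from None

    def variability_model(self) -> VariabilityModel:
        try:
            return derive_sigmas(
                self.subject_profile(),
                self.variability.cv_t,
                self.variability.cv_m,
                RoundingMode(self.variability.rounding_mode),
            )
        except ValueError as exc:
            raise ConfigError(f"variability: {exc}") from None

    def stop_rule(self) -> StopRule:
        kind = self.protocol.stop_rule
        try:
            if kind == "fixed_stop":
                k = self.protocol.fixed_stop_k
                if k is None:
                    raise ValueError("stop_rule 'fixed_stop' requires protocol.fixed_stop_k")
                return StopRule.fixed(k)
            return StopRule(kind)
        except ValueError as exc:
            raise ConfigError(f"protocol.stop_rule: {exc}") from None

    def protocol_config(self, rc: Optional[float] = None) -> ProtocolConfig:
        rc = rc if rc is not None else self.protocol.rc
        if rc is None:
            raise ConfigError("protocol.rc is not set (grid-only configuration)")
        try:
            return ProtocolConfig(
                rc=rc,
                min_maneuvers=self.protocol.min_maneuvers,
                max_maneuvers=self.protocol.max_maneuvers,
                stop_rule=self.stop_rule(),
                nonrepeatable_policy=NonRepeatablePolicy(self.protocol.nonrepeatable_policy),
            )
        except ValueError as exc:
            raise ConfigError(f"protocol: {exc}") from None

    def rc_values(self) -> tuple[float, ...]:
        """The rc grid if configured, else the single rc."""
        if self.protocol.rc_grid:
            return tuple(self.protocol.rc_grid)
        return (self.protocol.rc,)

    def simulation_config(self, seed: Optional[int] = None) -> SimulationConfig:
        return SimulationConfig(
            subject=self.subject_profile(),
            variability=self.variability_model(),
            n_tests=self.simulation.n_tests,
            n_maneuvers=self.protocol.max_maneuvers,
            seed=self.simulation.seed if seed is None else seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _build_section(name: str, cls, data: Mapping[str, Any]):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"{name}: unknown key(s) {sorted(unknown)}; allowed keys are {sorted(allowed)}"
        )
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    return cls(**coerced)


def load_config(path: Union[str, Path, None] = None, overrides: Optional[Mapping] = None) -> RunConfig:
    """Load a YAML or JSON run configuration, filling defaults.

    ``overrides`` (same nested shape) are applied on top of the file;
    a missing or empty file yields the full default configuration.
    """
    data: dict[str, Any] = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping, got {type(loaded).__name__}")
        data = loaded
    if overrides:
        for section, values in overrides.items():
            data.setdefault(section, {})
            if not isinstance(data[section], dict):
                raise ConfigError(f"{section}: must be a mapping")
            data[section] = {**data[section], **values}

    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(
            f"unknown section(s) {sorted(unknown)}; allowed sections are {sorted(_SECTIONS)}"
        )
    sections = {}
    for name, cls in _SECTIONS.items():
        body = data.get(name, {})
        if body is None:
            body = {}
        if not isinstance(body, Mapping):
            raise ConfigError(f"{name}: must be a mapping, got {type(body).__name__}")
        sections[name] = _build_section(name, cls, body)
    return RunConfig(**sections)
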