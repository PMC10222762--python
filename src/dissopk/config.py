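"""Study configuration: defaults, validation, YAML round trip.

A :class:`StudyConfig` holds every tunable number of the pipeline in named
sections (drug, disposition, absorption, doe, population, fixtures) plus
the master seed.  All defaults are the desvenlafaxine study values; a
loaded file may override any subset, and unknown keys are rejected rather
than ignored so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .pk import AbsorptionParams, DispositionParams, DrugProperties

__all__ = ["StudyConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """Unknown key or out-of-range value in a study configuration."""


@dataclass(frozen=True)
class DoESettings:
    n_units: int = 6
    noise_cv: float = 0.03

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ConfigError("doe.n_units must be >= 1")
        if not 0 <= self.noise_cv <= 0.5:
            raise ConfigError("doe.noise_cv must lie in [0, 0.5]")


@dataclass(frozen=True)
class PopulationSettings:
    n_subjects: int = 25
    n_trials: int = 10
    cv_cl: float = 0.25
    cv_vc: float = 0.25
    cv_ka: float = 0.15
    cv_within: float = 0.18

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ConfigError("population.n_subjects must be >= 3")
        if self.n_trials < 0:
            raise ConfigError("population.n_trials must be >= 0")
        for name in ("cv_cl", "cv_vc", "cv_ka", "cv_within"):
            if getattr(self, name) < 0:
                raise ConfigError(f"population.{name} must be >= 0")


@dataclass(frozen=True)
class FixtureSettings:
    sa_v_sensitivity: float = 2.0
    plasma_noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.sa_v_sensitivity < 0:
            raise ConfigError("fixtures.sa_v_sensitivity must be >= 0")
        if self.plasma_noise_cv < 0:
            raise ConfigError("fixtures.plasma_noise_cv must be >= 0")


_SECTIONS = {
    "drug": DrugProperties,
    "disposition": DispositionParams,
    "absorption": AbsorptionParams,
    "doe": DoESettings,
    "population": PopulationSettings,
    "fixtures": FixtureSettings,
}


@dataclass(frozen=True)
class StudyConfig:
    drug: DrugProperties = field(default_factory=DrugProperties)
    disposition: DispositionParams = field(default_factory=DispositionParams)
    absorption: AbsorptionParams = field(default_factory=AbsorptionParams)
    doe: DoESettings = field(default_factory=DoESettings)
    population: PopulationSettings = field(default_factory=PopulationSettings)
    fixtures: FixtureSettings = field(default_factory=FixtureSettings)
    seed: int = 0
    provenance: dict = field(default_factory=dict, compare=False)

    def to_dict(self) -> dict:
        out: dict = {"seed": self.seed}
        for name in _SECTIONS:
            out[name] = dataclasses.asdict(getattr(self, name))
        return out

    def config_hash(self) -> str:
        """Short stable hash for output-file provenance lines."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> StudyConfig:
    """Load a YAML study config; absent keys fall back to defaults.

    Unknown sections/keys and invariant violations raise ``ConfigError``.
    ``provenance`` records whether each section key came from the file or
    from the shipped defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigError(f"{path}: unknown config section(s) {sorted(unknown)}")
    kwargs: dict = {}
    provenance: dict = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name) or {}
        if not isinstance(section, dict):
            raise ConfigError(f"{path}: section '{name}' must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(section) - valid
        if bad:
            raise ConfigError(f"{path}: unknown key(s) in [{name}]: {sorted(bad)}")
        try:
            kwargs[name] = cls(**section)
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"{path}: invalid [{name}] value: {exc}") from exc
        provenance[name] = {
            k: ("user" if k in section else "default") for k in valid
        }
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"{path}: seed must be an integer")
    provenance["seed"] = "user" if "seed" in raw else "default"
    return StudyConfig(seed=seed, provenance=provenance, **kwargs)


def save_config(config: StudyConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
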