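"""Framework configuration: loading, validation and defaults.

A single YAML or JSON file with sections ``membership``, ``diffusion``,
``enzyme``, ``regeneration``, ``fusion``, ``optimizer`` and
``evaluation`` configures every stage.  Validation enforces the model
constraints before any work: all membership weights non-negative and
sigmas positive, the decay parameter within (0, 1], and fusion weights
non-negative and normalized.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from neutrodent.diffusion import DiffusionParams
from neutrodent.enzymes import ImmuneParams, KineticParams, LactoferrinParams
from neutrodent.membership import MembershipParams
from neutrodent.regeneration import RegenParams

__all__ = ["Config", "ConfigError", "FusionConfig", "EvaluationConfig", "load_config"]


class ConfigError(ValueError):
    """A configuration value violates a model constraint."""


@dataclass
class FusionConfig:
    """Fusion weights (clinical, imaging, genetic, behavioral) and scoring rule."""

    weights: tuple[float, float, float, float] = (0.35, 0.40, 0.15, 0.10)
    thresholds: tuple[float, float, float] = (0.25, 0.50, 0.75)
    decay_time: float = 0.0
    summarizer: str = "mean"  # or "top_decile"

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights):
            raise ConfigError("fusion weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigError(
                f"fusion weights must be normalized (sum to 1), got sum "
                f"{sum(self.weights)!r}"
            )
        t = self.thresholds
        if not (0.0 < t[0] < t[1] < t[2] < 1.0):
            raise ConfigError("diagnosis thresholds must be strictly increasing in (0, 1)")
        if self.summarizer not in ("mean", "top_decile"):
            raise ConfigError(f"unknown summarizer {self.summarizer!r}")
        if self.decay_time < 0:
            raise ConfigError("decay_time must be non-negative")


@dataclass
class EvaluationConfig:
    n_bins: int = 10
    dca_thresholds: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75)

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ConfigError("n_bins must be positive")
        if any(not (0.0 < t < 1.0) for t in self.dca_thresholds):
            raise ConfigError("DCA thresholds must lie strictly inside (0, 1)")


@dataclass
class Config:
    """Full framework configuration with validated sections."""

    membership: MembershipParams = field(default_factory=MembershipParams)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    kinetic: KineticParams = field(default_factory=KineticParams)
    immune: ImmuneParams = field(default_factory=ImmuneParams)
    lactoferrin: LactoferrinParams = field(default_factory=LactoferrinParams)
    regeneration: RegenParams = field(default_factory=RegenParams)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    optimizer: dict = field(default_factory=dict)


_SECTION_TYPES = {
    "membership": MembershipParams,
    "diffusion": DiffusionParams,
    "enzyme": KineticParams,
    "immune": ImmuneParams,
    "lactoferrin": LactoferrinParams,
    "regeneration": RegenParams,
    "fusion": FusionConfig,
    "evaluation": EvaluationConfig,
}

_SECTION_FIELDS = {
    "membership": "membership",
    "diffusion": "diffusion",
    "enzyme": "kinetic",
    "immune": "immune",
    "lactoferrin": "lactoferrin",
    "regeneration": "regeneration",
    "fusion": "fusion",
    "evaluation": "evaluation",
}


def _build(cls, section: str, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    try:
        return cls(**coerced)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid section {section!r}: {exc}") from exc


def load_config(path: str | Path | None = None, overrides: Optional[dict] = None) -> Config:
    """Load and validate a configuration file (YAML or JSON).

    ``overrides`` is a nested dict merged over the file contents;
    with no path, defaults (optionally overridden) are returned.
    """
    data: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration root must be a mapping")
    for section, values in (overrides or {}).items():
        data.setdefault(section, {}).update(values)

    kwargs: dict[str, Any] = {}
    for section, values in data.items():
        if section == "optimizer":
            kwargs["optimizer"] = dict(values)
            continue
        if section not in _SECTION_TYPES:
            raise ConfigError(f"unknown configuration section {section!r}")
        if not isinstance(values, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        kwargs[_SECTION_FIELDS[section]] = _build(_SECTION_TYPES[section], section, values)
    return Config(**kwargs)
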