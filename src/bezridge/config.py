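"""YAML run configuration: per-module sections merged over defaults."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

from .bezier import FitConfig
from .matching import MatchConfig
from .preprocess import PreprocessConfig
from .restoration import RestoreConfig

log = logging.getLogger("bezridge")


class ConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    pattern: str = "whorl"
    height: int = 300
    width: int = 300
    ridge_period: float = 8.0
    noise_level: float = 0.0


@dataclass
class DamageConfig:
    patches: int = 1
    min_axis: float = 6.0
    max_axis: float = 24.0
    fill: float | None = None


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    damage: DamageConfig = field(default_factory=DamageConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    restore: RestoreConfig = field(default_factory=RestoreConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    log_level: str = "INFO"
    seed: int = 0


_SECTION_TYPES = {f.name: f for f in dataclasses.fields(RunConfig)}


def _apply_section(obj, section: str, data: dict):
    valid = {f.name: f for f in dataclasses.fields(type(obj))}
    for key, value in data.items():
        if key not in valid:
            raise ConfigError(f"unknown key {section}.{key}")
        current = getattr(obj, key)
        if isinstance(current, bool) and not isinstance(value, bool):
            raise ConfigError(f"type mismatch for {section}.{key}: expected bool")
        if isinstance(current, (int, float)) and not isinstance(value, (int, float)):
            raise ConfigError(f"type mismatch for {section}.{key}: expected number, "
                              f"got {type(value).__name__}")
        if isinstance(current, str) and not isinstance(value, str):
            raise ConfigError(f"type mismatch for {section}.{key}: expected string")
        if isinstance(current, list) and not isinstance(value, list):
            raise ConfigError(f"type mismatch for {section}.{key}: expected list")
        setattr(obj, key, value)
    try:
        post = getattr(obj, "__post_init__", None)
        if post:
            post()
    except ValueError as exc:
        raise ConfigError(f"invalid value in section {section}: {exc}") from exc


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Defaults, overlaid with a YAML file and then explicit overrides.

    Unknown keys or mistyped values raise :class:`ConfigError` naming the
    offending key. The effective configuration is echoed to the run log.
    """
    cfg = RunConfig()
    layers = []
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("top level of the config file must be a mapping")
        layers.append(data)
    if overrides:
        layers.append(overrides)
    for layer in layers:
        for section, content in layer.items():
            if section in ("log_level", "seed"):
                setattr(cfg, section, content)
                continue
            if section not in _SECTION_TYPES:
                raise ConfigError(f"unknown section {section}")
            if not isinstance(content, dict):
                raise ConfigError(f"section {section} must be a mapping")
            _apply_section(getattr(cfg, section), section, content)
    log.debug("effective config: %s", cfg)
    return cfg


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage derived seed (stable hash of the stage name, below 2^31)."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % 1000003
    return (seed * 1000003 + h) % (2**31 - 1)
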