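"""Structured configuration: YAML round-trip of all simulator parameters."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .control import ControlPolicy
from .corpus import ConfigError
from .dynamics import DynamicsParams
from .engine import EngineConfig
from .targeting import PerceptualSpan, StrategyProfile, TargetingConfig

__all__ = ["CorpusConfig", "SimulationConfig", "load_config", "save_config", "default_config"]


@dataclass(frozen=True)
class CorpusConfig:
    """Arguments of the synthetic-corpus generator (see ``corpus.generate_corpus``)."""

    n_sentences: int = 250
    words_per_sentence: tuple[int, int] = (8, 12)
    anomaly_rate: float = 0.35
    length_range: tuple[int, int] = (2, 12)
    length_mode: int = 5
    pred_beta: tuple[float, float] = (1.2, 3.0)
    helpful_target_rate: float = 0.2
    mismatch_range: tuple[float, float] = (0.1, 0.7)


@dataclass(frozen=True)
class SimulationConfig:
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    policy: ControlPolicy = field(default_factory=ControlPolicy)
    targeting: TargetingConfig = field(default_factory=TargetingConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)


def _build(cls, data: dict, path: str) -> Any:
    fields = {f.name: f for f in dataclasses.fields(cls)}
    nested = {"span": PerceptualSpan, "strategy": StrategyProfile}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown configuration key {path}{key}")
        if key in nested and isinstance(value, dict):
            kwargs[key] = _build(nested[key], value, f"{path}{key}.")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


_SECTIONS = {
    "corpus": CorpusConfig,
    "dynamics": DynamicsParams,
    "policy": ControlPolicy,
    "targeting": TargetingConfig,
    "engine": EngineConfig,
}


def load_config(path: str | Path | None = None) -> SimulationConfig:
    """Load a YAML configuration; missing sections and keys take defaults."""
    if path is None:
        return SimulationConfig()
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration file must be a mapping of sections")
    kwargs = {}
    for section, value in data.items():
        if section not in _SECTIONS:
            raise ConfigError(f"unknown configuration section {section!r}")
        kwargs[section] = _build(_SECTIONS[section], value or {}, f"{section}.")
    return SimulationConfig(**kwargs)


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(_to_plain(config), sort_keys=False), encoding="utf-8"
    )


def default_config() -> SimulationConfig:
    return SimulationConfig()
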