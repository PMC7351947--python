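"""Run configuration: YAML-backed, validated, round-trip lossless."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple

import yaml

from .evaluate import SimConfigLike

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "config_hash"]


class ConfigError(ValueError):
    """Malformed or schema-violating configuration."""


@dataclass
class IndicatorConfig:
    polarity: str = "positive"
    F_max: float = 100.0
    sensitivity: float = 0.2


@dataclass
class SweepGridConfig:
    densities: List[int] = field(default_factory=lambda: [1, 2, 4, 8, 16])
    sensitivities: List[float] = field(default_factory=lambda: [0.2, 1.0])
    polarities: List[str] = field(default_factory=lambda: ["positive", "negative"])
    n_reps: int = 20
    error_target: float = 0.5


@dataclass
class RunConfig:
    """Top-level configuration for the CLI pipeline.

    ``simulation`` defaults describe the reference recording (40,000 frames at
    400 Hz, 100 spikes per neuron on average); the sweep configuration scales
    these down explicitly where needed.
    """

    simulation: SimConfigLike = field(default_factory=SimConfigLike)
    indicator: IndicatorConfig = field(default_factory=IndicatorConfig)
    sweep: SweepGridConfig = field(default_factory=SweepGridConfig)
    base_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["fov"] = list(d["simulation"]["fov"])
        return d


_NESTED = {"simulation": SimConfigLike, "indicator": IndicatorConfig, "sweep": SweepGridConfig}


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under '{path}'")
    kwargs = {}
    for key, value in data.items():
        nested_cls = _NESTED.get(key) if cls is RunConfig else None
        if nested_cls is not None:
            if not isinstance(value, dict):
                raise ConfigError(f"'{path}.{key}' must be a mapping")
            kwargs[key] = _build(nested_cls, value, f"{path}.{key}")
        else:
            kwargs[key] = value
    try:
        obj = cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid values under '{path}': {exc}") from exc
    return obj


def _validate(cfg: RunConfig) -> None:
    sim = cfg.simulation
    if isinstance(sim.fov, list):
        sim.fov = tuple(sim.fov)
    checks = [
        (sim.n_frames > 0, "simulation.n_frames must be positive"),
        (sim.frame_rate_hz > 0, "simulation.frame_rate_hz must be positive"),
        (sim.mean_spikes >= 0, "simulation.mean_spikes must be non-negative"),
        (sim.noise_coeff >= 0, "simulation.noise_coeff must be non-negative"),
        (sim.noise_model in ("proportional", "additive"), "simulation.noise_model invalid"),
        (cfg.indicator.polarity in ("positive", "negative"), "indicator.polarity invalid"),
        (cfg.indicator.sensitivity > 0, "indicator.sensitivity must be positive"),
        (len(cfg.sweep.densities) > 0, "sweep.densities must be non-empty"),
        (all(p in ("positive", "negative") for p in cfg.sweep.polarities), "sweep.polarities invalid"),
        (cfg.sweep.n_reps >= 1, "sweep.n_reps must be >= 1"),
        (0 <= cfg.base_seed < 2**31, "base_seed must fit in a signed 32-bit integer"),
    ]
    bad = [msg for ok, msg in checks if not ok]
    if bad:
        raise ConfigError("; ".join(bad))


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    cfg = _build(RunConfig, data, "config")
    _validate(cfg)
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable content hash of a configuration (for run manifests)."""
    import hashlib

    canonical = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
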