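"""Run configuration: one flat key space over simulation + training.

A run config is a YAML (or JSON — YAML is a superset) mapping whose
keys are the union of the simulation settings (:class:`SimSpec`) and
the training/construction settings (:class:`TrainConfig`); ``seed`` is
shared by both.  Unknown keys are rejected so typos fail loudly.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .simulate import SimSpec
from .train import TrainConfig

__all__ = ["RunConfig", "load_config"]

_SIM_KEYS = set(SimSpec.__dataclass_fields__)
_TRAIN_KEYS = set(TrainConfig.__dataclass_fields__)
KNOWN_KEYS = _SIM_KEYS | _TRAIN_KEYS


@dataclass
class RunConfig:
    """Validated pair of simulation and training settings."""

    sim: SimSpec
    train: TrainConfig

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping")
        unknown = set(data) - KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = SimSpec(**{k: v for k, v in data.items() if k in _SIM_KEYS})
        train = TrainConfig(**{k: v for k, v in data.items() if k in _TRAIN_KEYS})
        return cls(sim=sim, train=train)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"no such config file: {path}")
        data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        return cls.from_mapping(data)

    def with_overrides(self, **overrides) -> "RunConfig":
        """Apply non-None CLI overrides on top of the file values."""
        data = self.to_dict()
        for k, v in overrides.items():
            if v is None:
                continue
            if k not in KNOWN_KEYS:
                raise ValueError(f"unknown config key: {k}")
            data[k] = v
        return RunConfig.from_mapping(data)

    def to_dict(self) -> dict:
        merged = dataclasses.asdict(self.sim)
        merged.update(dataclasses.asdict(self.train))
        return merged

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    base = RunConfig.from_file(path) if path else RunConfig.from_mapping({})
    return base.with_overrides(**overrides)
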