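"""YAML configuration mapped onto the dataclass configs.

Top-level sections: ``synth``, ``disnet``, ``lsnet``, ``fusion``,
``train``, ``data``, ``eval``.  Unknown keys are rejected so typos fail
loudly; missing keys keep the dataclass defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, TypeVar

import yaml

from .models import DisnetConfig, FusionConfig, LsnetConfig, ModelConfig
from .synth import SynthConfig
from .training import TrainConfig

__all__ = [
    "load_config",
    "dataclass_from_dict",
    "model_config_from_dict",
    "synth_config_from_dict",
    "train_config_from_dict",
]

T = TypeVar("T")


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return cfg


def dataclass_from_dict(cls: type[T], d: dict[str, Any] | None) -> T:
    d = dict(d or {})
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise KeyError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    # YAML gives lists where the dataclasses expect tuples
    for f in dataclasses.fields(cls):
        if f.name in d and isinstance(d[f.name], list) and "tuple" in str(f.type):
            d[f.name] = tuple(d[f.name])
    return cls(**d)


def model_config_from_dict(cfg: dict) -> ModelConfig:
    return ModelConfig(
        disnet=dataclass_from_dict(DisnetConfig, cfg.get("disnet")),
        lsnet=dataclass_from_dict(LsnetConfig, cfg.get("lsnet")),
        fusion=dataclass_from_dict(FusionConfig, cfg.get("fusion")),
        use_lstm=bool(cfg.get("use_lstm", True)),
        seed=int(cfg.get("seed", 0)),
    )


def synth_config_from_dict(cfg: dict) -> SynthConfig:
    d = dict(cfg.get("synth") or {})
    if "class_profiles" in d:
        d["class_profiles"] = [
            {int(ch): tuple(spec) for ch, spec in prof.items()}
            for prof in d["class_profiles"]
        ]
    return dataclass_from_dict(SynthConfig, d)


def train_config_from_dict(cfg: dict) -> TrainConfig:
    return dataclass_from_dict(TrainConfig, cfg.get("train"))
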