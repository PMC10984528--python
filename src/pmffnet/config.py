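"""YAML configuration: model / data / train sections with defaults."""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .model import ModelConfig
from .phantom import PhantomConfig
from .train import TrainConfig


def default_config() -> dict:
    return {
        "model": ModelConfig().to_dict(),
        "data": {
            "side": 384,
            "mean": [0.5, 0.5, 0.5],
            "std": [0.25, 0.25, 0.25],
            "phantom": asdict(PhantomConfig()),
        },
        "train": asdict(TrainConfig()),
    }


def _deep_update(base: dict, override: dict) -> dict:
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path=None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        _deep_update(cfg, user)
    return cfg


def model_config(cfg: dict) -> ModelConfig:
    return ModelConfig.from_dict(cfg["model"])


def phantom_config(cfg: dict) -> PhantomConfig:
    d = dict(cfg["data"]["phantom"])
    for key in ("image_size", "area_fraction"):
        d[key] = tuple(d[key])
    return PhantomConfig(**d)


def train_config(cfg: dict) -> TrainConfig:
    d = dict(cfg["train"])
    d["betas"] = tuple(d["betas"])
    return TrainConfig(**d)
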