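"""YAML configuration loading for training and backbone settings.

A config file holds two optional mappings::

    backbone:
      preset: tiny
      width: 32
      pathways: 3
    train:
      lr: 0.004
      epochs: 15
      loss_name: vdiou
      seed: 0

Unknown keys raise immediately so typos do not silently fall back to
defaults.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .backbone import BackboneConfig
from .detector import TrainConfig

__all__ = ["load_configs", "dump_configs"]


def _build(cls, mapping: dict):
    valid = {f.name for f in fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    for f in fields(cls):
        if f.name in kwargs and isinstance(f.default, tuple):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def load_configs(path) -> tuple[TrainConfig, BackboneConfig]:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    train = _build(TrainConfig, raw.get("train", {}) or {})
    backbone = _build(BackboneConfig, raw.get("backbone", {}) or {})
    return train, backbone


def dump_configs(path, train: TrainConfig, backbone: BackboneConfig) -> None:
    payload = {"train": {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in vars(train).items()},
               "backbone": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in vars(backbone).items()}}
    Path(path).write_text(yaml.safe_dump(payload))
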