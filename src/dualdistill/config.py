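"""YAML configuration loading for the command-line interface.

Layout::

    train:            # any TrainConfig field, e.g. epochs, batch_size, ...
      epochs: 15
    loss:             # any ObjectiveConfig field
      alpha: 0.3
      components: [SD, RGSD, AGSD]
      rgsd: {mode: frobenius, reduction: frobenius, detach_teacher: true}
      agsd: {normalize: true, detach_teacher: false, sigmoid: false}
    model:
      widths: [4, 8, 16, 32]
      students: [1, 2, 3]
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .objective import ObjectiveConfig
from .trainer import TrainConfig

__all__ = ["load_config", "build_objective", "build_train_config"]


def _flatten_loss(section: dict) -> dict:
    out = {}
    for key, value in (section or {}).items():
        if key in ("rgsd", "agsd") and isinstance(value, dict):
            for sub, v in value.items():
                out[f"{key}_{sub}"] = v
        else:
            out[key] = value
    if "components" in out and not isinstance(out["components"], frozenset):
        out["components"] = frozenset(out["components"])
    if "rgsd_stages" in out and out["rgsd_stages"] is not None:
        out["rgsd_stages"] = tuple(out["rgsd_stages"])
    if "agsd_stages" in out and out["agsd_stages"] is not None:
        out["agsd_stages"] = tuple(out["agsd_stages"])
    out.pop("agsd_sigmoid", None)  # consumed by the model builder
    return out


def build_objective(section: dict) -> ObjectiveConfig:
    return ObjectiveConfig(**_flatten_loss(section))


def build_train_config(section: dict) -> TrainConfig:
    section = dict(section or {})
    for key in ("milestones", "mean", "std", "crop_area", "crop_aspect"):
        if key in section and section[key] is not None:
            section[key] = tuple(section[key])
    return TrainConfig(**section)


def load_config(path: str | Path) -> tuple[TrainConfig, ObjectiveConfig, dict]:
    """Read a YAML file into (TrainConfig, ObjectiveConfig, model section)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    train_cfg = build_train_config(raw.get("train", {}))
    objective = build_objective(raw.get("loss", {}))
    model_section = dict(raw.get("model", {}))
    return train_cfg, objective, model_section
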