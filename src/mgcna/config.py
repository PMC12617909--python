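"""YAML run configuration: defaults < config file < command-line overrides.

Schema (all keys optional)::

    seed: 0
    views: [mirna_seq, mirna_gene, mirna_mda, drug_struct, drug_gene, drug_mda]
    thresholds: {mirna_seq: 0.5, ..., drug_mda: 0.5}
    model:
      h: 512
      layer_dims: [256, 128]
      dropout: 0.5
      fusion: attention          # or: sum
      decoder_mode: multi_relational   # or: plain_concat
      lr: 0.0005
      weight_decay: 0.0005
      epochs: 500
    synthetic: {n_mirnas: 200, n_drugs: 40, ...}
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .model import ModelConfig
from .synthetic import SyntheticConfig
from .views import ALL_VIEWS

_MODEL_KEYS = {f.name for f in dataclasses.fields(ModelConfig)}
_SYN_KEYS = {f.name for f in dataclasses.fields(SyntheticConfig)}


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level of the config must be a mapping")
    unknown = set(data) - {"seed", "views", "thresholds", "model", "synthetic"}
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return data


def model_config_from(cfg: dict) -> ModelConfig:
    section = dict(cfg.get("model") or {})
    unknown = set(section) - _MODEL_KEYS
    if unknown:
        raise ValueError(f"unknown model config keys {sorted(unknown)}")
    if "layer_dims" in section and section["layer_dims"] is not None:
        section["layer_dims"] = tuple(section["layer_dims"])
    return ModelConfig(**section)


def synthetic_config_from(cfg: dict, seed: int) -> SyntheticConfig:
    section = dict(cfg.get("synthetic") or {})
    unknown = set(section) - _SYN_KEYS
    if unknown:
        raise ValueError(f"unknown synthetic config keys {sorted(unknown)}")
    section.setdefault("seed", seed)
    return SyntheticConfig(**section)


def views_from(cfg: dict) -> list[str] | None:
    views = cfg.get("views")
    if views is None:
        return None
    unknown = set(views) - set(ALL_VIEWS)
    if unknown:
        raise ValueError(f"unknown view names {sorted(unknown)}")
    return list(views)


def resolved_config(cfg: dict, seed: int, model: ModelConfig) -> dict:
    """Full effective configuration, written alongside every run's outputs."""
    return {
        "seed": seed,
        "views": views_from(cfg) or list(ALL_VIEWS),
        "thresholds": cfg.get("thresholds") or {},
        "model": dataclasses.asdict(model.resolved()),
    }


def dump_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
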