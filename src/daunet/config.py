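"""YAML (de)serialization of run configurations.

A run configuration is a nested set of dataclasses; this module flattens it
to a plain-YAML mapping and reconstructs it, normalizing the handful of
fields that YAML cannot represent natively (tuples).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .data import PhantomConfig
from .network import ModelConfig
from .objectives import LossConfig
from .train import RunConfig

__all__ = ["run_config_to_yaml", "run_config_from_yaml", "load_run_config", "save_run_config"]

_TUPLE_FIELDS = {
    "input_size": int,
    "component_weights": float,
    "lesion_area_fraction": float,
    "split_fractions": float,
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def _coerce(cls, payload: dict | None):
    if payload is None:
        return None
    kwargs = {}
    valid = {f.name for f in dataclasses.fields(cls)}
    for key, value in payload.items():
        if key not in valid:
            raise ValueError(f"unknown {cls.__name__} field {key!r}")
        if key in _TUPLE_FIELDS and value is not None:
            value = tuple(_TUPLE_FIELDS[key](v) for v in value)
        kwargs[key] = value
    return cls(**kwargs)


def run_config_to_yaml(cfg: RunConfig) -> str:
    return yaml.safe_dump(_to_plain(cfg), sort_keys=False)


def run_config_from_yaml(text: str) -> RunConfig:
    payload = yaml.safe_load(text) or {}
    payload["model"] = _coerce(ModelConfig, payload.get("model"))
    payload["loss"] = _coerce(LossConfig, payload.get("loss"))
    payload["phantoms"] = _coerce(PhantomConfig, payload.get("phantoms"))
    if payload["model"] is None:
        payload.pop("model")
    if payload["loss"] is None:
        payload.pop("loss")
    cfg = _coerce(RunConfig, payload)
    cfg.validate()
    return cfg


def save_run_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(run_config_to_yaml(cfg))


def load_run_config(path) -> RunConfig:
    return run_config_from_yaml(Path(path).read_text())
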