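"""YAML round-tripping for scheme configurations."""

from __future__ import annotations

from dataclasses import asdict, fields

import yaml

from .selection import SchemeConfig

__all__ = ["load_config", "save_config", "config_to_dict", "config_from_dict"]


def config_to_dict(config: SchemeConfig) -> dict:
    return asdict(config)


def _to_tuple(value):
    if isinstance(value, list):
        return tuple(_to_tuple(v) for v in value)
    return value


def config_from_dict(data: dict) -> SchemeConfig:
    known = {f.name for f in fields(SchemeConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SchemeConfig(**{k: _to_tuple(v) for k, v in data.items()})


def save_config(config: SchemeConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def load_config(path) -> SchemeConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)
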