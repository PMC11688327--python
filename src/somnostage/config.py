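"""YAML run configuration: validated loading of all stage configs.

A run config file may contain any of the sections ``channels``, ``stft``,
``model`` (with nested ``encoder_single``, ``encoder_fused``, ``mfem``),
``train`` and ``synthetic``.  Unknown keys are rejected with the offending
key named first in the error, and dotted ``--set`` overrides are supported.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from somnostage.io import ChannelSpec
from somnostage.model import ModelConfig
from somnostage.nn.encoder import EncoderConfig
from somnostage.nn.mfem import MfemConfig
from somnostage.tf import StftConfig
from somnostage.train import TrainConfig


@dataclass
class SyntheticConfig:
    """Generator parameters for the ``simulate`` command."""

    n_subjects: int = 1
    n_epochs: int = 100
    osa: bool = False
    seed: int = 0


@dataclass
class RunConfig:
    channels: ChannelSpec = field(default_factory=ChannelSpec)
    stft: StftConfig = field(default_factory=StftConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)


_NESTED = {
    "model": {"encoder_single": EncoderConfig, "encoder_fused": EncoderConfig, "mfem": MfemConfig},
}


def _build(cls, payload: dict, path: str) -> Any:
    if not isinstance(payload, dict):
        raise ValueError(f"config section {path!r} must be a mapping, got {type(payload).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(payload) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key {path}.{sorted(unknown)[0]}")
    kwargs = {}
    for key, value in payload.items():
        sub = _NESTED.get(path.split(".")[-1], {}).get(key)
        if sub is not None and isinstance(value, dict):
            kwargs[key] = _build(sub, value, f"{path}.{key}")
        elif key == "names" and isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: list[str] | None = None) -> RunConfig:
    """Load a RunConfig from YAML, then apply dotted ``key=value`` overrides."""
    payload: dict = {}
    if path is not None:
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
    for override in overrides or []:
        if "=" not in override:
            raise ValueError(f"override must be key=value, got {override!r}")
        key, _, raw = override.partition("=")
        node = payload
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = yaml.safe_load(raw)

    sections = {f.name: f.default_factory for f in dataclasses.fields(RunConfig)}
    unknown = set(payload) - set(sections)
    if unknown:
        raise ValueError(f"unknown config key {sorted(unknown)[0]}")
    kwargs = {}
    for name, factory in sections.items():
        if name in payload:
            kwargs[name] = _build(type(factory()), payload[name], name)
    return RunConfig(**kwargs)


def config_digest(cfg: RunConfig) -> str:
    """Stable hash of a full run configuration (for run manifests)."""
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
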