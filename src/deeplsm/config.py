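"""Structured experiment configuration with strict validation.

The YAML config mirrors the reference parameter table: every dynamical
constant (threshold, time constants, connectivity, plasticity, scaling
targets) is pre-populated with its default, unknown keys are rejected
with their full key path, and out-of-range values raise named errors.
One master seed deterministically derives the per-module seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .network import DeepLSMConfig, derive_seed
from .neurodynamics import LIFParams, STPParams, TraceParams
from .plasticity import STDPParams
from .reservoir import ConnectivityParams
from .synthetic_data import SyntheticTaskSpec

__all__ = [
    "ExperimentConfig",
    "ReadoutConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "config_hash",
    "derive_seed",
]


class ConfigError(ValueError):
    """Configuration validation failure, reporting the offending key path."""


@dataclass(frozen=True)
class ReadoutConfig:
    """Attention-readout training settings."""

    lr: float = 0.05
    epochs: int = 500
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("lr must be non-negative")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")


@dataclass(frozen=True)
class ExperimentConfig:
    """Top-level experiment description: network + task + readout + seed."""

    network: DeepLSMConfig = field(default_factory=DeepLSMConfig)
    task: SyntheticTaskSpec = field(default_factory=SyntheticTaskSpec)
    readout: ReadoutConfig = field(default_factory=ReadoutConfig)
    wta_epochs: int = 1
    seed: int = 0
    out_dir: str = "runs"


_TUPLE_FIELDS = {"hidden_sizes", "wta_sizes", "norm_targets", "dims", "ei_ratio"}


def _build(dc_type, data, path: str):
    """Recursively build a dataclass from a mapping, rejecting unknown keys."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(dc_type)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"{path or 'config'}: unknown key(s) {sorted(unknown)}"
        )
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        value = data[name]
        sub_path = f"{path}.{name}" if path else name
        if is_dataclass(f.type) or (isinstance(f.type, str) and f.type in _NESTED):
            sub_type = _NESTED[f.type] if isinstance(f.type, str) else f.type
            kwargs[name] = _build(sub_type, value, sub_path)
        elif name in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return dc_type(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path or 'config'}: {exc}") from exc


_NESTED = {
    "DeepLSMConfig": DeepLSMConfig,
    "SyntheticTaskSpec": SyntheticTaskSpec,
    "ReadoutConfig": ReadoutConfig,
    "LIFParams": LIFParams,
    "STPParams": STPParams,
    "TraceParams": TraceParams,
    "ConnectivityParams": ConnectivityParams,
    "STDPParams": STDPParams,
}


def load_config(path: str | Path | None = None,
                data: dict | None = None) -> ExperimentConfig:
    """Load and validate a YAML experiment config.

    An empty (or absent) file yields the full defaults.  Unknown keys,
    wrong types, and out-of-range values raise :class:`ConfigError`
    naming the key path.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            text = Path(path).read_text()
            data = yaml.safe_load(text) or {}
    return _build(ExperimentConfig, data, "")


def _to_dict(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    return obj


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    """Write the config back to YAML (round-trips through load_config)."""
    Path(path).write_text(yaml.safe_dump(_to_dict(config), sort_keys=True))


def config_hash(config: ExperimentConfig) -> str:
    """Stable short hash identifying a config (for run provenance)."""
    blob = json.dumps(_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
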