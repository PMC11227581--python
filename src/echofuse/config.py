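"""Run configuration: defaults, YAML loading, overrides, validation.

Precedence is defaults < config file < command-line overrides.  The
resolved tree is flat-validated against the default schema (unknown keys
and type mismatches are rejected by name) and hashed so run directories
are self-describing.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "DataError", "load_config", "DEFAULTS",
           "EXIT_OK", "EXIT_CONFIG", "EXIT_DATA", "EXIT_NUMERIC"]

EXIT_OK, EXIT_CONFIG, EXIT_DATA, EXIT_NUMERIC = 0, 2, 3, 4


class ConfigError(ValueError):
    """Invalid configuration (exit code 2)."""


class DataError(RuntimeError):
    """Missing or malformed input data (exit code 3)."""


DEFAULTS: dict = {
    "seed": 0,
    "data": {
        "n_scans": 6,
        "duration_s": 60.0,
        "fps": 4.0,
        "image_size": 64,
        "sample_rate": 24_000,
        "p_offtopic": 0.3,
        "p_invalid_token": 0.1,
        "noise_sigma": 0.05,
    },
    "model": {
        "embed_dim": 32,
        "backbone": "tiny",
        "preprocess": "desk",
    },
    "objective": {
        "alpha": 0.25,
        "beta": 0.25,
        "gamma": 0.25,
        "delta": 0.25,
        "tau": 0.1,
        "contrastive_mode": "infonce",
    },
    "train": {
        "variant": "full",
        "epochs": 30,
        "batch_size": 40,
        "lr": 0.05,
        "lr_decay_every": 20,
        "momentum": 0.9,
        "n_examples": 400,
        "p_negative": 0.5,
        "heldout_fraction": 0.2,
        "sig_lambda": 0.0,
    },
    "finetune": {
        "epochs": 12,
        "lr": 0.01,
        "batch_size": 40,
    },
}


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration tree plus its content hash."""

    tree: dict
    config_hash: str

    def __getitem__(self, key):
        return self.tree[key]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.tree, sort_keys=True)

    def dump(self, path):
        Path(path).write_text(self.to_yaml(), encoding="utf-8")


def _flatten(tree: dict, prefix: str = ""):
    for k, v in tree.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            yield from _flatten(v, f"{key}.")
        else:
            yield key, v


def _set_path(tree: dict, dotted: str, value):
    parts = dotted.split(".")
    node = tree
    for p in parts[:-1]:
        if p not in node or not isinstance(node[p], dict):
            raise ConfigError(f"unknown configuration key: {dotted!r}")
        node = node[p]
    leaf = parts[-1]
    if leaf not in node:
        raise ConfigError(f"unknown configuration key: {dotted!r}")
    default = node[leaf]
    if default is not None and value is not None:
        if isinstance(default, bool) != isinstance(value, bool):
            raise ConfigError(f"type mismatch for {dotted!r}: expected bool")
        if isinstance(default, (int, float)) and not isinstance(value, (int, float)):
            raise ConfigError(
                f"type mismatch for {dotted!r}: expected number, got {type(value).__name__}"
            )
        if isinstance(default, str) and not isinstance(value, str):
            raise ConfigError(
                f"type mismatch for {dotted!r}: expected string, got {type(value).__name__}"
            )
    node[leaf] = value


def _parse_override(text: str):
    if "=" not in text:
        raise ConfigError(f"override must look like key=value, got {text!r}")
    key, raw = text.split("=", 1)
    try:
        value = yaml.safe_load(raw)
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse override value {raw!r}: {e}") from None
    return key.strip(), value


def _validate(tree: dict):
    obj = tree["objective"]
    total = obj["alpha"] + obj["beta"] + obj["gamma"] + obj["delta"]
    if any(obj[k] < 0 for k in ("alpha", "beta", "gamma", "delta")):
        raise ConfigError("objective weights must be non-negative")
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(
            f"objective.alpha+beta+gamma+delta must sum to 1, got {total!r}"
        )
    if tree["data"]["duration_s"] <= 0 or tree["data"]["fps"] <= 0:
        raise ConfigError("data.duration_s and data.fps must be positive")
    if tree["train"]["variant"] not in ("base", "contrastive", "spatial", "text", "full"):
        raise ConfigError(f"unknown train.variant {tree['train']['variant']!r}")


def load_config(path=None, overrides=()) -> RunConfig:
    """Resolve a run configuration: defaults < file < overrides."""
    tree = copy.deepcopy(DEFAULTS)
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise DataError(f"config file not found: {p}")
        loaded = yaml.safe_load(p.read_text(encoding="utf-8"))
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {p} must contain a mapping")
        for key, value in _flatten(loaded):
            _set_path(tree, key, value)
    for ov in overrides:
        key, value = _parse_override(ov) if isinstance(ov, str) else ov
        _set_path(tree, key, value)
    _validate(tree)
    canonical = json.dumps(tree, sort_keys=True)
    return RunConfig(tree=tree, config_hash=hashlib.sha256(canonical.encode()).hexdigest())
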