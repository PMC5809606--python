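"""Run configuration loading, validation, and reproducibility manifests.

Configs are YAML (or JSON, a YAML subset) mappings with one block per
pipeline stage; every run writes a manifest recording the config hash,
global seed and library versions so outputs can be reproduced
byte-identically.  All stage randomness is derived from the single
global seed via named substreams.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, fields, is_dataclass
from pathlib import Path
from typing import Any

import numpy as np
import scipy
import yaml

__all__ = ["load_config", "validate_block", "substream_seed", "write_manifest"]


class ConfigError(ValueError):
    """Invalid or malformed run configuration."""


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            cfg = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed config {path}: {exc}") from exc
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def validate_block(cfg: dict, block: str, cls: type) -> Any:
    """Build a dataclass from a config block, rejecting unknown keys."""
    if not is_dataclass(cls):
        raise TypeError(f"{cls} is not a dataclass")
    raw = cfg.get(block, {})
    if not isinstance(raw, dict):
        raise ConfigError(f"config block '{block}' must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown keys in '{block}': {sorted(unknown)}")
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{block}' block: {exc}") from exc


def substream_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


def _config_hash(cfg: dict) -> str:
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_manifest(outdir: str | Path, cfg: dict, seed: int, stage: str) -> Path:
    from cytoaml import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config_sha256_16": _config_hash(cfg),
        "seed": seed,
        "versions": {
            "cytoaml": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
    }
    path = outdir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
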