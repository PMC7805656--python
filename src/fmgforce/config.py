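"""Run configuration: YAML round-trip and content hashing.

Every output artifact records the hash of the configuration that produced
it, so a results table can be regenerated from its config alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Short stable hash of a JSON-serializable configuration mapping."""
    try:
        canon = json.dumps(cfg, sort_keys=True, default=str)
    except TypeError as exc:
        raise ConfigError(f"configuration is not serializable: {exc}") from exc
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return cfg


def save_config(cfg: Mapping[str, Any], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
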