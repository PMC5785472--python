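"""Configuration loading.

All tunable rule tables (domain anchors, AT/KR signature windows, docking
heuristic, element masses, adduct definitions, starter-unit library) live in
YAML files shipped with the package.  ``load_config`` returns the defaults,
optionally deep-merged with a user YAML so individual keys can be overridden
without restating the whole table.
"""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["default_config", "load_config", "config_hash"]

_cached_defaults: dict[str, Any] | None = None


def _read_packaged_yaml(name: str) -> dict[str, Any]:
    text = resources.files("pksmine.data").joinpath(name).read_text(encoding="utf-8")
    return yaml.safe_load(text)


def default_config() -> dict[str, Any]:
    """Return a deep copy of the packaged default configuration."""
    global _cached_defaults
    if _cached_defaults is None:
        cfg = _read_packaged_yaml("signatures.yaml")
        cfg.update(_read_packaged_yaml("chemistry.yaml"))
        _cached_defaults = cfg
    return copy.deepcopy(_cached_defaults)


def _deep_merge(base: dict[str, Any], extra: Mapping[str, Any]) -> dict[str, Any]:
    for key, value in extra.items():
        if isinstance(value, Mapping) and isinstance(base.get(key), dict):
            _deep_merge(base[key], value)
        else:
            base[key] = copy.deepcopy(value)
    return base


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load the default configuration, overridden by an optional user YAML."""
    cfg = default_config()
    if path is not None:
        with open(path, encoding="utf-8") as handle:
            user = yaml.safe_load(handle) or {}
        if not isinstance(user, Mapping):
            raise ValueError(f"config file {path} must contain a YAML mapping")
        _deep_merge(cfg, user)
    return cfg


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Stable short hash of a configuration, for report provenance."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
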