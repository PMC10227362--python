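"""Run configuration: YAML files mirroring the CLI flags.

Every CLI flag overrides the corresponding config key; a serialised config
plus a seed reproduces a run byte-identically, and each command logs the
SHA-256 hash of its effective configuration so runs are auditable.
"""

from __future__ import annotations

import hashlib
import json
import os

import yaml

__all__ = ["load_config", "merge_options", "config_hash", "parse_tool_spec"]


def load_config(path: str | os.PathLike | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return data


def merge_options(config: dict, **cli_options) -> dict:
    """Config keys overridden by any CLI option that was actually given."""
    merged = dict(config)
    for key, value in cli_options.items():
        if value is not None:
            merged[key] = value
    return merged


def config_hash(options: dict) -> str:
    canon = json.dumps(options, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def parse_tool_spec(spec: str, with_dialect: bool) -> tuple:
    """Parse ``label=path`` or ``label=dialect=path`` tool declarations."""
    parts = spec.split("=")
    want = 3 if with_dialect else 2
    if len(parts) != want:
        form = "label=dialect=path" if with_dialect else "label=path"
        raise ValueError(f"tool spec {spec!r} must have the form {form}")
    return tuple(parts)
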