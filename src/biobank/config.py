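"""YAML configuration for the CLI.

A single file declares the database path, lake root and import mode, the
acting user, and entry points that register applications and signals.
Environment variables (``BIOBANK_DB``, ``BIOBANK_LAKE``, ``BIOBANK_USER``)
override the file so scripted deployments need no file edits.
"""

from __future__ import annotations

import importlib
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import yaml


@dataclass
class CliConfig:
    database: str = "biobank.sqlite"
    lake_root: str = "lake"
    import_mode: str = "MOVE"
    user: str = "admin"
    id_template: str = "{prefix}-{counter:04d}"
    apps: list[str] = field(default_factory=list)      # "module:callable" entries
    signals: list[str] = field(default_factory=list)   # "module:callable" entries
    patterns: dict[str, str] = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path | None) -> "CliConfig":
        data: dict[str, Any] = {}
        if path is not None and Path(path).exists():
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        cfg = cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})
        cfg.database = os.environ.get("BIOBANK_DB", cfg.database)
        cfg.lake_root = os.environ.get("BIOBANK_LAKE", cfg.lake_root)
        cfg.user = os.environ.get("BIOBANK_USER", cfg.user)
        return cfg


def load_entry_point(spec: str) -> Callable:
    module_name, _, attr = spec.partition(":")
    if not attr:
        raise ValueError(f"entry point {spec!r} must look like module:callable")
    module = importlib.import_module(module_name)
    return getattr(module, attr)


def connect(config: CliConfig):
    """Build a wired :class:`~biobank.core.Biobank` from a config."""
    from .core import Biobank

    bank = Biobank(lake_root=config.lake_root, db_path=config.database,
                   import_mode=config.import_mode,
                   current_user=config.user, id_template=config.id_template)
    for spec in config.apps:
        load_entry_point(spec)(bank.apps)
    for spec in config.signals:
        signal = load_entry_point(spec)(bank)
        if signal is not None:
            for sig in signal if isinstance(signal, list) else [signal]:
                bank.signals.register(sig)
    return bank
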