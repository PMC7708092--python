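"""The :class:`Biobank` facade wiring all services together.

A Biobank owns one embedded database, one data lake, one application
registry, a signal registry (receiving every status transition from imports
and analyses), an auto-merger, and a scheduler.  The CLI and the tests both
go through this object so there is a single wiring of the dispatch chain.
"""

from __future__ import annotations

from pathlib import Path

from .applications import AppRegistry, ExperimentTuple
from .automations import AutoMerger, Scheduler, SignalRegistry
from .datalake import DataLake, StorageConfig, storage_path
from .db import Database
from .metadata import MetadataStore


class Biobank:
    def __init__(self, lake_root: str | Path, db_path: str = ":memory:",
                 import_mode: str = "MOVE", enforce_permissions: bool = True,
                 current_user: str = "admin",
                 id_template: str = "{prefix}-{counter:04d}"):
        self.db = Database(db_path)
        self.store = MetadataStore(self.db,
                                   enforce_permissions=enforce_permissions,
                                   id_template=id_template)
        self.signals = SignalRegistry()
        self.config = StorageConfig(Path(lake_root), import_mode)
        self.config.lake_root.mkdir(parents=True, exist_ok=True)
        self.lake = DataLake(self.store, self.config,
                             dispatch=self.signals.dispatch)
        self.apps = AppRegistry(self.store, self.lake,
                                dispatch=self.signals.dispatch)
        self.merger = AutoMerger(self.apps)
        self.scheduler = Scheduler()
        self.current_user = current_user

    def close(self) -> None:
        self.db.close()

    # ------------------------------------------------- project directories

    def get_or_create_project(self, title: str, actor: str | None = None,
                              **fields) -> dict:
        for rec in self.db.all("project"):
            if rec["title"] == title:
                return rec
        return self.store.create_record(
            "project", {"title": title, **fields},
            actor=actor or self.current_user)

    def sync_project_dirs(self, project: dict) -> Path:
        """Maintain a per-project tree of symlinks to every current
        SUCCEEDED analysis directory; idempotent, stale links removed."""
        root = storage_path("projects", project["pk"], self.config) / "analyses"
        root.mkdir(parents=True, exist_ok=True)
        wanted: dict[Path, Path] = {}
        for rec in self.db.all("analysis"):
            if rec.get("superseded") or rec["status"] != "SUCCEEDED":
                continue
            if project["system_id"] not in rec.get("projects", []):
                continue
            app = rec["application"]
            app_dir = root / app["name"]
            exps = [self.db.get("experiment", t)["custom_id"]
                    for t in rec["targets"]]
            link = app_dir / ("__".join(exps) or rec["system_id"])
            wanted[link] = Path(rec["storage_url"])
        # drop stale links, (re)point current ones
        for existing in root.rglob("*"):
            if existing.is_symlink() and existing not in wanted:
                existing.unlink()
        for link, target in wanted.items():
            link.parent.mkdir(parents=True, exist_ok=True)
            if link.is_symlink():
                if link.resolve() == target.resolve():
                    continue
                link.unlink()
            link.symlink_to(target)
        # prune emptied application directories
        for sub in sorted(root.glob("*")):
            if sub.is_dir() and not any(sub.iterdir()):
                sub.rmdir()
        return root

    # ---------------------------------------------------------- conveniences

    def query(self, kind: str, **filters):
        return self.store.query(kind, filters)

    def tuple_for(self, targets, references=()) -> ExperimentTuple:
        return ExperimentTuple.make(targets, references)
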