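"""Application SDK: versioned, assembly-aware pipeline deployment.

An *application* is a registered, versioned wrapper around an external tool.
Its identity is (name, version, assembly) — assembly-aware versioning,
because results produced against different genome builds are not
comparable.  Applications plan experiment tuples (targets vs references),
validate them, create *analyses* deduplicated on (identity, canonical
tuple), construct shell commands, and submit them through a pluggable
executor.  Every analysis freezes its configuration (settings, reference
asset checksums, application identity) at creation for a complete audit
trail, and superseded runs are archived to time-stamped legacy directories.
"""

from __future__ import annotations

import datetime
import re
import shutil
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Callable

import yaml

from .datalake import DataLake, lock_tree, storage_path, unlock_path
from .errors import (
    DesignError,
    DuplicateApplicationError,
    ExecutorError,
    IllegalTransitionError,
    NotFoundError,
    NotImportedError,
    NotReadyError,
    TupleRejectedError,
    UnknownResultError,
    ValidationError,
    VersionOrderError,
)
from .metadata import MetadataStore
from .schema import SCALAR_TYPES

#: legal analysis lifecycle transitions (FAILED→STAGED is the manual retry)
TRANSITIONS: dict[str, set[str]] = {
    "CREATED": {"STAGED"},
    "STAGED": {"SUBMITTED"},
    "SUBMITTED": {"STARTED", "FAILED"},
    "STARTED": {"SUCCEEDED", "FAILED"},
    "SUCCEEDED": set(),
    "FAILED": {"STAGED"},
}

NON_TERMINAL = ("CREATED", "STAGED", "SUBMITTED", "STARTED")


@dataclass(frozen=True)
class ResultSpec:
    kind: str                    # file | number | boolean | text
    path: str | None = None      # relative path template for file results


@dataclass
class ApplicationDescriptor:
    name: str
    version: str
    assembly: str | None = None          # None = assembly-agnostic
    species: str = ""
    settings: dict[str, Any] = dc_field(default_factory=dict)
    results_spec: dict[str, ResultSpec] = dc_field(default_factory=dict)
    build_command: Callable[..., str] | None = None
    parse_results: Callable[..., dict[str, Any]] | None = None
    validate_tuple: Callable[..., Any] | None = None
    merge_project: Callable[..., Any] | None = None
    merge_individual: Callable[..., Any] | None = None

    @property
    def identity(self) -> tuple[str, str, str | None]:
        return (self.name, self.version, self.assembly)

    @property
    def identity_map(self) -> dict[str, Any]:
        return {"name": self.name, "version": self.version,
                "assembly": self.assembly}

    @property
    def label(self) -> str:
        tag = f"{self.name}/{self.version}"
        return f"{tag}/{self.assembly}" if self.assembly else tag


@dataclass(frozen=True)
class ExperimentTuple:
    """Ordered targets/references, canonicalized by system_id sort."""

    targets: tuple[str, ...]
    references: tuple[str, ...] = ()

    @classmethod
    def make(cls, targets, references=()) -> "ExperimentTuple":
        targets = tuple(sorted(t["system_id"] if isinstance(t, dict) else t
                               for t in targets))
        references = tuple(sorted(r["system_id"] if isinstance(r, dict) else r
                                  for r in references))
        if not targets:
            raise ValidationError("tuple targets must be non-empty")
        if set(targets) & set(references):
            raise ValidationError("targets and references must be disjoint")
        return cls(targets, references)


@dataclass
class PlanResult:
    tuples: list[ExperimentTuple] = dc_field(default_factory=list)
    skipped: list[tuple[dict, str]] = dc_field(default_factory=list)


@dataclass
class RunReport:
    created: list[dict] = dc_field(default_factory=list)
    reused: list[dict] = dc_field(default_factory=list)
    skipped: list[tuple[ExperimentTuple, str]] = dc_field(default_factory=list)
    submitted: list[dict] = dc_field(default_factory=list)


@dataclass
class SupersedeReport:
    superseded: list[dict] = dc_field(default_factory=list)
    created: list[dict] = dc_field(default_factory=list)
    legacy_dirs: list[Path] = dc_field(default_factory=list)


def parse_version(version: str) -> tuple[int, ...]:
    parts = re.findall(r"\d+", version)
    if not parts:
        raise ValidationError(f"unparseable version {version!r}")
    return tuple(int(p) for p in parts)


class AppRegistry:
    """Registered applications plus the analysis engine over a store + lake."""

    def __init__(self, store: MetadataStore, lake: DataLake,
                 dispatch: Callable[[dict, str, str], object] | None = None):
        self.store = store
        self.lake = lake
        self.dispatch = dispatch
        self._descriptors: dict[tuple, ApplicationDescriptor] = {}
        self._pending: dict[int, tuple[object, str]] = {}  # handle -> (executor, analysis id)

    # -------------------------------------------------------- registration

    def register_application(self, app: ApplicationDescriptor
                             ) -> ApplicationDescriptor:
        if app.identity in self._descriptors:
            raise DuplicateApplicationError(f"{app.label} already registered")
        for hook in ("build_command", "parse_results"):
            if not callable(getattr(app, hook)):
                raise ValidationError(f"{app.label} missing {hook} hook")
        for key, spec in app.results_spec.items():
            if spec.kind not in SCALAR_TYPES | {"file"}:
                raise ValidationError(f"result {key!r} has invalid kind {spec.kind!r}")
        # identity is persisted; a persisted record without in-memory hooks
        # means a fresh session re-attaching the same application
        existing = [a for a in self.store.db.all("application")
                    if (a["name"], a["version"], a.get("assembly")) == app.identity]
        if existing:
            self._descriptors[app.identity] = app
            return app
        self.store.create_record("application", {
            "name": app.name, "version": app.version, "assembly": app.assembly,
            "species": app.species, "settings": app.settings,
            "results_keys": sorted(app.results_spec),
        }, actor="admin")
        self._descriptors[app.identity] = app
        return app

    def get(self, name: str, version: str, assembly: str | None = None
            ) -> ApplicationDescriptor:
        try:
            return self._descriptors[(name, version, assembly)]
        except KeyError:
            raise NotFoundError(f"application {name}/{version}"
                                f"{'/' + assembly if assembly else ''} "
                                f"not registered") from None

    # ------------------------------------------------------------- planning

    def plan_tuples(self, app: ApplicationDescriptor, experiments: list[dict],
                    design: str, pool: list[dict] | None = None) -> PlanResult:
        """Turn a cohort into analysis tuples for an experimental design."""
        if not experiments:
            raise DesignError("no experiments to plan over")
        plan = PlanResult()
        if design == "SINGLE_TARGET":
            plan.tuples = [ExperimentTuple.make([e]) for e in experiments]
        elif design == "TARGET_VS_POOL":
            if not pool:
                raise DesignError("TARGET_VS_POOL requires a reference pool")
            pool_ids = [p["system_id"] for p in pool]
            for exp in experiments:
                if exp["system_id"] in pool_ids:
                    plan.skipped.append((exp, "experiment is part of the pool"))
                else:
                    plan.tuples.append(ExperimentTuple.make([exp], pool_ids))
        elif design == "PAIRED_BY_INDIVIDUAL":
            plan = self._plan_paired(experiments)
        else:
            raise DesignError(f"unknown design {design!r}")
        return plan

    def _individual_of(self, experiment: dict) -> str:
        sample = self.store.db.get("sample", experiment["sample"])
        return sample["individual"]

    def _plan_paired(self, experiments: list[dict]) -> PlanResult:
        plan = PlanResult()
        annotated = []
        for exp in experiments:
            sample = self.store.db.get("sample", exp["sample"])
            cls = sample.get("sample_class")
            if cls not in ("TUMOR", "NORMAL"):
                plan.skipped.append((exp, f"sample_class {cls!r} is not "
                                          f"TUMOR or NORMAL"))
                continue
            annotated.append((exp, cls, sample["individual"]))
        by_individual: dict[str, dict[str, list[dict]]] = {}
        for exp, cls, ind in annotated:
            by_individual.setdefault(ind, {"TUMOR": [], "NORMAL": []})[cls].append(exp)
        for ind in sorted(by_individual):
            groups = by_individual[ind]
            if not groups["NORMAL"]:
                for t in groups["TUMOR"]:
                    plan.skipped.append((t, "no matched normal for individual"))
            if not groups["TUMOR"]:
                for n in groups["NORMAL"]:
                    plan.skipped.append((n, "no tumor for individual"))
            for tumor in groups["TUMOR"]:
                for normal in groups["NORMAL"]:
                    plan.tuples.append(ExperimentTuple.make([tumor], [normal]))
        return plan

    # ------------------------------------------------------------- analyses

    def find_analysis(self, app: ApplicationDescriptor,
                      tup: ExperimentTuple) -> dict | None:
        for rec in self.store.db.all("analysis"):
            if rec.get("superseded"):
                continue
            if (rec["application"] == app.identity_map
                    and tuple(rec["targets"]) == tup.targets
                    and tuple(rec.get("references", ())) == tup.references):
                return rec
        return None

    def get_or_create_analysis(self, app: ApplicationDescriptor,
                               tup: ExperimentTuple,
                               actor: str = "admin") -> tuple[dict, bool]:
        """Return the existing non-superseded analysis for (identity,
        canonical tuple), or create one with a frozen config snapshot."""
        if app.identity not in self._descriptors:
            raise NotFoundError(f"{app.label} not registered")
        exps = [self.store.db.get("experiment", sid)
                for sid in (*tup.targets, *tup.references)]
        not_imported = [e["custom_id"] for e in exps
                        if e["import_status"] != "IMPORTED"]
        if not_imported:
            raise NotImportedError(f"experiments without imported data: "
                                   f"{not_imported}")
        if app.validate_tuple is not None:
            reason = app.validate_tuple(app, self._tuple_records(tup))
            if isinstance(reason, str) and reason:
                raise TupleRejectedError(reason)
        existing = self.find_analysis(app, tup)
        if existing is not None:
            return existing, False
        projects = sorted({p for e in exps for p in e["projects"]})
        individuals = sorted({self._individual_of(e) for e in exps})
        snapshot = {
            "application": app.identity_map,
            "settings": dict(app.settings),
            "reference_checksums": {
                key: rec["checksum"]
                for key, rec in sorted(
                    self.lake.references_for(app.assembly or "NONE").items())
            },
        }
        analysis = self.store.create_record("analysis", {
            "application": app.identity_map,
            "targets": list(tup.targets),
            "references": list(tup.references),
            "projects": projects,
            "individuals": individuals,
            "status": "CREATED",
            "results": {},
            "config_snapshot": snapshot,
        }, actor=actor)
        storage = storage_path("analyses", analysis["pk"], self.lake.config)
        analysis = self.store.update_record(
            "analysis", analysis["system_id"], {"storage_url": str(storage)},
            actor=actor)
        return analysis, True

    def _tuple_records(self, tup: ExperimentTuple) -> dict[str, list[dict]]:
        return {
            "targets": [self.store.db.get("experiment", s) for s in tup.targets],
            "references": [self.store.db.get("experiment", s)
                           for s in tup.references],
        }

    def _raw_paths(self, experiment: dict) -> list[str]:
        return [self.store.db.get("data_asset", a)["lake_path"]
                for a in experiment.get("raw_data", [])]

    # ------------------------------------------------------------------ run

    def run(self, app: ApplicationDescriptor, tuples: list[ExperimentTuple],
            executor, dry_run: bool = False, actor: str = "admin") -> RunReport:
        """Validate, create/reuse, stage and submit analyses for tuples.

        Succeeded (and in-flight) analyses are never resubmitted; dry runs
        stop after the command is written to disk.
        """
        report = RunReport()
        for tup in tuples:
            try:
                analysis, created = self.get_or_create_analysis(
                    app, tup, actor=actor)
            except (TupleRejectedError, NotImportedError) as exc:
                report.skipped.append((tup, str(exc)))
                continue
            (report.created if created else report.reused).append(analysis)
            if analysis["status"] == "CREATED":
                analysis = self._stage(app, analysis, actor)
            if analysis["status"] != "STAGED" or dry_run:
                continue
            analysis = self.set_status(analysis, "SUBMITTED", actor)
            try:
                handle = executor.submit(
                    self._command_of(analysis), analysis["storage_url"], {})
            except ExecutorError as exc:
                (Path(analysis["storage_url"]) / "logs").mkdir(
                    parents=True, exist_ok=True)
                (Path(analysis["storage_url"]) / "logs" /
                 "submission_error.log").write_text(str(exc) + "\n")
                self.set_status(analysis, "FAILED", actor)
                continue
            self._pending[handle] = (executor, analysis["system_id"])
            report.submitted.append(analysis)
        return report

    def _stage(self, app: ApplicationDescriptor, analysis: dict,
               actor: str) -> dict:
        storage = Path(analysis["storage_url"])
        (storage / "results").mkdir(parents=True, exist_ok=True)
        (storage / "logs").mkdir(parents=True, exist_ok=True)
        tup = ExperimentTuple(tuple(analysis["targets"]),
                              tuple(analysis.get("references", ())))
        records = self._tuple_records(tup)
        inputs = {
            "targets": [{"experiment": e, "paths": self._raw_paths(e)}
                        for e in records["targets"]],
            "references": [{"experiment": e, "paths": self._raw_paths(e)}
                           for e in records["references"]],
            "settings": analysis["config_snapshot"]["settings"],
            "reference_assets": {
                key: rec["lake_path"]
                for key, rec in self.lake.references_for(
                    app.assembly or "NONE").items()},
            "outdir": str(storage / "results"),
        }
        command = app.build_command(app, analysis, inputs)
        (storage / "head_job.sh").write_text("#!/bin/sh\n" + command + "\n")
        with open(storage / "settings.yaml", "w") as fh:
            yaml.safe_dump(analysis["config_snapshot"], fh, sort_keys=True)
        return self.set_status(analysis, "STAGED", actor)

    def _command_of(self, analysis: dict) -> str:
        script = Path(analysis["storage_url"]) / "head_job.sh"
        return f"sh {script}"

    def wait(self, poll_interval: float = 0.05, timeout: float = 300.0) -> None:
        """Drive pending jobs to completion, applying status transitions."""
        deadline = time.monotonic() + timeout
        while self._pending:
            if time.monotonic() > deadline:
                raise ExecutorError("timed out waiting for jobs")
            for handle in list(self._pending):
                executor, analysis_id = self._pending[handle]
                status = executor.poll(handle)
                if not status.done:
                    continue
                del self._pending[handle]
                analysis = self.store.db.get("analysis", analysis_id)
                analysis = self.set_status(analysis, "STARTED", "admin")
                outcome = "SUCCEEDED" if status.exit_code == 0 else "FAILED"
                self.set_status(analysis, outcome, "admin")
            if self._pending:
                time.sleep(poll_interval)

    # --------------------------------------------------------------- status

    def set_status(self, analysis: dict, new_status: str,
                   actor: str = "admin") -> dict:
        """Apply a lifecycle transition; parse results and write-lock output
        on success; every persisted transition is dispatched to signals."""
        old = analysis["status"]
        if new_status not in TRANSITIONS.get(old, set()):
            raise IllegalTransitionError(f"{old} -> {new_status} not allowed")
        changes: dict[str, Any] = {"status": new_status}
        if new_status == "SUCCEEDED":
            app = self._descriptors.get(tuple(
                analysis["application"][k] for k in ("name", "version", "assembly")))
            if app is not None:
                changes["results"] = self._parse_results(app, analysis)
        record = self.store.update_record(
            "analysis", analysis["system_id"], changes, actor=actor)
        if new_status == "SUCCEEDED":
            storage = Path(record["storage_url"])
            if storage.exists():
                lock_tree(storage)
        if self.dispatch is not None:
            self.dispatch(record, old, new_status)
        return record

    def _parse_results(self, app: ApplicationDescriptor,
                       analysis: dict) -> dict[str, Any]:
        outdir = Path(analysis["storage_url"]) / "results"
        results = app.parse_results(app, analysis, str(outdir)) or {}
        unknown = set(results) - set(app.results_spec)
        if unknown:
            raise ValidationError(f"results {sorted(unknown)} not declared "
                                  f"in {app.label} results_spec")
        for key, spec in app.results_spec.items():
            if key not in results:
                continue
            if spec.kind == "file":
                path = Path(results[key])
                if not path.exists():
                    raise ValidationError(f"result file {key!r} missing: {path}")
        return results

    # ---------------------------------------------------------- supersession

    def supersede(self, app_old: ApplicationDescriptor,
                  app_new: ApplicationDescriptor,
                  tuples: list[ExperimentTuple] | None = None,
                  actor: str = "admin") -> SupersedeReport:
        """Replace analyses of a buggy version: archive each old output to a
        time-stamped legacy directory and create fresh analyses under the
        new version."""
        if (app_old.name, app_old.assembly) != (app_new.name, app_new.assembly):
            raise VersionOrderError("supersession requires same name and assembly")
        if parse_version(app_new.version) <= parse_version(app_old.version):
            raise VersionOrderError(
                f"new version {app_new.version} must exceed {app_old.version}")
        if app_new.identity not in self._descriptors:
            raise NotFoundError(f"{app_new.label} not registered")
        wanted = None if tuples is None else {
            (t.targets, t.references) for t in tuples}
        report = SupersedeReport()
        for rec in list(self.store.db.all("analysis")):
            if rec.get("superseded") or rec["application"] != app_old.identity_map:
                continue
            if rec.get("project_level") or rec.get("individual_level"):
                continue  # merge outputs are superseded by re-merging

            key = (tuple(rec["targets"]), tuple(rec.get("references", ())))
            if wanted is not None and key not in wanted:
                continue
            stamp = datetime.datetime.now(datetime.timezone.utc).strftime(
                "%Y-%m-%dT%H:%M:%S.%fZ")
            legacy = self._archive(Path(rec["storage_url"]), stamp)
            rec = self.store.update_record("analysis", rec["system_id"], {
                "superseded": True, "superseded_at": stamp}, actor=actor)
            report.superseded.append(rec)
            if legacy is not None:
                report.legacy_dirs.append(legacy)
            new_analysis, _ = self.get_or_create_analysis(
                app_new, ExperimentTuple(*key), actor=actor)
            report.created.append(new_analysis)
        return report

    @staticmethod
    def _archive(storage: Path, stamp: str) -> Path | None:
        if not storage.exists():
            return None
        legacy = storage / "__legacy__" / stamp
        legacy.mkdir(parents=True, exist_ok=True)
        for entry in sorted(storage.iterdir()):
            if entry.name == "__legacy__":
                continue
            _unlock_tree(entry)  # outputs are read-only after success
            shutil.move(str(entry), str(legacy / entry.name))
        return legacy

    # --------------------------------------------------------------- results

    def get_result(self, analysis: dict, key: str) -> Any:
        app_keys = None
        app = self._descriptors.get(tuple(
            analysis["application"][k] for k in ("name", "version", "assembly")))
        if app is not None:
            app_keys = set(app.results_spec)
        if app_keys is not None and key not in app_keys:
            raise UnknownResultError(f"result key {key!r} not declared for "
                                     f"{analysis['application']}")
        if analysis["status"] != "SUCCEEDED":
            raise NotReadyError(f"analysis {analysis['system_id']} is "
                                f"{analysis['status']}, not SUCCEEDED")
        if key not in analysis["results"]:
            raise UnknownResultError(f"result {key!r} not present")
        value = analysis["results"][key]
        if app is not None and app.results_spec[key].kind == "file":
            if not Path(value).exists():
                raise NotFoundError(f"result file {value} missing on disk")
        return value

    def latest_analysis(self, name: str, assembly: str | None,
                        tup: ExperimentTuple) -> dict:
        """Resolve the current (non-superseded) analysis for a tuple across
        versions — supersession makes this the newest version."""
        candidates = [
            rec for rec in self.store.db.all("analysis")
            if not rec.get("superseded")
            and rec["application"]["name"] == name
            and rec["application"]["assembly"] == assembly
            and tuple(rec["targets"]) == tup.targets
            and tuple(rec.get("references", ())) == tup.references
        ]
        if not candidates:
            raise NotFoundError(f"no current analysis of {name} for {tup}")
        return max(candidates,
                   key=lambda r: parse_version(r["application"]["version"]))


def _unlock_tree(path: Path) -> None:
    if path.is_file() or path.is_symlink():
        if not path.is_symlink():
            unlock_path(path)
        return
    unlock_path(path)
    for sub in path.rglob("*"):
        if not sub.is_symlink():
            unlock_path(sub)
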