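"""Individual-centric metadata registry.

The registry persists individuals, samples, aliquots, experiments, projects
and their supporting vocabularies (techniques, platforms, diseases), enforces
validation and referential integrity on every write, refuses deletions that
would dangle references, and keeps a full append-only audit trail from which
any previous state can be recovered.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Callable, Iterable

import pandas as pd

from . import permissions, schema
from .db import Database
from .errors import (
    DanglingReferenceError,
    FilterError,
    FormatError,
    NotFoundError,
    PermissionDenied,
    ProtectedError,
    ValidationError,
    VersionError,
)

BATCH_MANDATORY = (
    "individual_id", "sample_id", "experiment_id",
    "technique", "platform", "species", "center",
)
BATCH_OPTIONAL = ("sex", "sample_class", "disease", "collection_state",
                  "technique_category")

#: action required to write each non-metadata kind (metadata kinds use
#: REGISTER_METADATA; admin bypasses everything)
_KIND_ACTIONS = {
    "analysis": "RUN_ANALYSIS",
    "application": "RUN_ANALYSIS",
    "data_asset": "IMPORT_DATA",
    "reference_asset": "IMPORT_DATA",
}


@dataclass
class BatchReport:
    created: list[dict] = dc_field(default_factory=list)
    rejected: list[tuple[int, str]] = dc_field(default_factory=list)


class MetadataStore:
    """Validated CRUD + audit trail + queries over a :class:`Database`."""

    def __init__(self, db: Database, enforce_permissions: bool = True,
                 id_template: str = "{prefix}-{counter:04d}"):
        self.db = db
        self.enforce_permissions = enforce_permissions
        self.id_template = id_template
        self._ensure_admin()

    # ------------------------------------------------------------------ users

    def _ensure_admin(self) -> None:
        """The single designated admin data-owner account, created at setup."""
        if not any(u.get("is_admin") for u in self.db.all("user")):
            rec = self.db.insert("user", {
                "username": "admin", "email": "", "roles": ["ENGINEER"],
                "is_admin": True, "overrides": [],
            })
            self.db.append_audit("user", rec["system_id"], "system", rec)

    @property
    def admin(self) -> dict:
        return next(u for u in self.db.all("user") if u.get("is_admin"))

    def get_user(self, username: str) -> dict:
        for u in self.db.all("user"):
            if u["username"] == username:
                return u
        raise NotFoundError(f"unknown user {username!r}")

    def check_permission(self, actor: str, action: str,
                         project: dict | None = None) -> None:
        if not self.enforce_permissions:
            return
        try:
            user = self.get_user(actor)
        except NotFoundError:
            raise PermissionDenied(f"unknown actor {actor!r}") from None
        decision = permissions.authorize(user, action, project=project)
        if not decision.allowed:
            raise PermissionDenied(decision.reason)

    def _check_write(self, kind: str, actor: str,
                     record: dict | None = None) -> None:
        if not self.enforce_permissions:
            return
        if kind in schema.METADATA_KINDS:
            self.check_permission(actor, "REGISTER_METADATA")
        elif kind in _KIND_ACTIONS:
            self.check_permission(actor, _KIND_ACTIONS[kind])
        else:  # user / schema_extension accounts: admin only
            user = self.get_user(actor)
            if not user.get("is_admin"):
                raise PermissionDenied(f"{kind} records require the admin account")

    # ------------------------------------------------- schema extensions

    def register_extension(self, entity_kind: str, field_name: str,
                           value_type: str, required: bool = False,
                           actor: str = "admin") -> dict:
        """Declare a custom field for an extensible kind."""
        if entity_kind not in schema.EXTENSIBLE_KINDS:
            raise ValidationError(f"kind {entity_kind!r} does not accept custom fields")
        if field_name in schema.fields_of(entity_kind):
            raise ValidationError(
                f"custom field {field_name!r} collides with a built-in field")
        return self.create_record("schema_extension", {
            "entity_kind": entity_kind, "field_name": field_name,
            "value_type": value_type, "required": required,
        }, actor=actor)

    def extensions_for(self, kind: str) -> dict[str, dict]:
        return {
            e["field_name"]: e
            for e in self.db.all("schema_extension")
            if e["entity_kind"] == kind
        }

    # ------------------------------------------------------------ validation

    def _next_custom_id(self, kind: str) -> str:
        prefix = schema.ID_PREFIXES.get(kind, kind[:1].upper())
        counter = self.db.next_counter(f"cid:{kind}")
        return self.id_template.format(prefix=prefix, counter=counter)

    def _validate(self, kind: str, data: dict[str, Any], *,
                  current: dict | None = None) -> dict[str, Any]:
        """Validate a full field map; returns the normalized record body."""
        specs = schema.fields_of(kind)
        extensions = self.extensions_for(kind) if kind in schema.EXTENSIBLE_KINDS else {}
        out: dict[str, Any] = {}
        custom = dict(data.get("custom_fields") or {})

        for key, value in data.items():
            if key in ("kind", "pk", "custom_fields"):
                continue
            if key not in specs:
                if key in extensions:
                    custom[key] = value
                    continue
                raise ValidationError(f"unknown field {key!r} for kind {kind!r}")
            out[key] = value

        for name, spec in specs.items():
            if name == "custom_fields":
                continue
            if name not in out or out[name] is None:
                if current is not None and name in current:
                    out[name] = current[name]
                    continue
                if spec.required:
                    raise ValidationError(f"{kind}.{name} is required")
                default = spec.default() if callable(spec.default) else spec.default
                out[name] = default
                continue
            value = out[name]
            if spec.immutable and current is not None and value != current.get(name):
                raise ValidationError(f"{kind}.{name} is immutable")
            self._check_field(kind, spec, value)

        if extensions or custom:
            for name, value in custom.items():
                if name not in extensions:
                    raise ValidationError(
                        f"undeclared custom field {name!r} for kind {kind!r}")
                if value is not None and not schema.check_scalar(
                        value, extensions[name]["value_type"]):
                    raise ValidationError(
                        f"custom field {name!r} must be {extensions[name]['value_type']}")
            for name, ext in extensions.items():
                if ext.get("required") and custom.get(name) is None:
                    raise ValidationError(f"required custom field {name!r} missing")
        if "custom_fields" in specs:
            out["custom_fields"] = custom

        self._kind_invariants(kind, out, current=current)
        return out

    def _check_field(self, kind: str, spec: schema.Field, value: Any) -> None:
        if spec.ref:
            ids = value if spec.many else [value]
            if not isinstance(ids, (list, tuple)):
                raise ValidationError(f"{kind}.{spec.name} must be a list of references")
            for sid in ids:
                if not self.db.exists(spec.ref, sid):
                    raise DanglingReferenceError(
                        f"{kind}.{spec.name} references missing {spec.ref} {sid!r}")
            return
        if spec.choices is not None and value not in spec.choices:
            raise ValidationError(
                f"{kind}.{spec.name}={value!r} not in {sorted(spec.choices)}")
        if spec.type == "number" and value is not None and not isinstance(
                value, (int, float)):
            raise ValidationError(f"{kind}.{spec.name} must be numeric")
        if spec.type == "boolean" and not isinstance(value, bool):
            raise ValidationError(f"{kind}.{spec.name} must be boolean")
        if spec.type == "map" and not isinstance(value, dict):
            raise ValidationError(f"{kind}.{spec.name} must be a mapping")
        if spec.type == "list" and not isinstance(value, (list, tuple)):
            raise ValidationError(f"{kind}.{spec.name} must be a list")

    def _kind_invariants(self, kind: str, out: dict, current: dict | None) -> None:
        if kind == "experiment":
            if not out.get("projects"):
                raise ValidationError("experiment requires at least one project")
            if out.get("aliquot"):
                aliquot = self.db.get("aliquot", out["aliquot"])
                if out.get("sample") and out["sample"] != aliquot["sample"]:
                    raise ValidationError(
                        "experiment links a sample and an aliquot of a different sample")
                out["sample"] = aliquot["sample"]
            imported = out.get("import_status") == "IMPORTED"
            if imported != bool(out.get("raw_data")):
                raise ValidationError(
                    "raw_data must be non-empty exactly when import_status is IMPORTED")
        if kind == "project" and not str(out.get("title") or "").strip():
            raise ValidationError("project title must be non-empty")
        if kind == "user":
            bad = set(out.get("roles") or []) - schema.ROLES
            if bad:
                raise ValidationError(f"unknown roles {sorted(bad)}")
        # uniqueness scan (metadata scale: hundreds of records)
        unique = schema.UNIQUE_TOGETHER.get(kind)
        if unique and all(out.get(f) is not None for f in unique):
            key = tuple(out[f] for f in unique)
            for other in self.db.all(kind):
                if current is not None and other["system_id"] == current["system_id"]:
                    continue
                if tuple(other.get(f) for f in unique) == key:
                    raise ValidationError(
                        f"duplicate {kind} for {dict(zip(unique, key))}")

    # ------------------------------------------------------------------ CRUD

    def create_record(self, kind: str, fields: dict[str, Any],
                      actor: str = "admin") -> dict:
        if kind not in schema.SCHEMAS:
            raise ValidationError(f"unknown entity kind {kind!r}")
        self._check_write(kind, actor)
        body = self._validate(kind, fields)
        if kind in schema.ID_PREFIXES and kind != "project" and not body.get("custom_id"):
            body["custom_id"] = self._next_custom_id(kind)
        if kind == "project" and body.get("creation_time") is None:
            body["creation_time"] = time.time()
        record = self.db.insert(kind, body)
        self.db.append_audit(kind, record["system_id"], actor, record)
        return record

    def update_record(self, kind: str, system_id: str,
                      changes: dict[str, Any], actor: str = "admin") -> dict:
        current = self.db.get(kind, system_id)
        if kind == "project":
            self.check_permission(actor, "EDIT_PROJECT", project=current)
        else:
            self._check_write(kind, actor)
        if not changes:
            return current
        merged = {k: v for k, v in current.items() if k not in ("kind", "pk")}
        extensions = self.extensions_for(kind) if kind in schema.EXTENSIBLE_KINDS else {}
        for key, value in changes.items():
            if key == "custom_fields":
                merged.setdefault("custom_fields", {})
                merged["custom_fields"] = {**merged["custom_fields"], **value}
            elif key in extensions:
                merged.setdefault("custom_fields", {})
                merged["custom_fields"] = {**merged["custom_fields"], key: value}
            else:
                merged[key] = value
        body = self._validate(kind, merged, current=current)
        record = dict(body, kind=kind, pk=current["pk"],
                      system_id=current["system_id"])
        if record == current:
            return current  # no-op: no new audit version
        self.db.replace(record)
        self.db.append_audit(kind, system_id, actor, record)
        return record

    def delete_record(self, kind: str, system_id: str,
                      actor: str = "admin") -> None:
        record = self.db.get(kind, system_id)
        if kind == "project":
            self.check_permission(actor, "EDIT_PROJECT", project=record)
        else:
            self._check_write(kind, actor)
        protected = self.referencing_records(kind, system_id)
        if protected:
            names = ", ".join(f"{k}:{sid}" for k, sid in protected)
            raise ProtectedError(
                f"cannot delete {kind} {system_id}: referenced by {names}",
                protected)
        self.db.delete(kind, system_id)

    def referencing_records(self, kind: str, system_id: str
                            ) -> list[tuple[str, str]]:
        """All (kind, system_id) pairs holding a reference to the target."""
        out = []
        for ref_kind, spec in schema.reference_fields():
            if spec.ref != kind:
                continue
            for rec in self.db.all(ref_kind):
                value = rec.get(spec.name)
                hit = system_id in value if spec.many else value == system_id
                if hit:
                    out.append((ref_kind, rec["system_id"]))
        return sorted(set(out))

    # ----------------------------------------------------------- audit trail

    def get_history(self, kind: str, system_id: str) -> list[dict]:
        history = self.db.history(kind, system_id)
        if not history:
            raise NotFoundError(f"{kind} {system_id!r} never existed")
        return history

    def recover_state(self, kind: str, system_id: str, version: int,
                      actor: str = "admin") -> dict:
        """Restore a past snapshot; the recovery itself appends a new version."""
        self._check_write(kind, actor)
        history = self.get_history(kind, system_id)
        by_version = {h["version"]: h for h in history}
        if version not in by_version:
            raise VersionError(
                f"{kind} {system_id} has versions 1..{len(history)}, not {version}")
        snapshot = dict(by_version[version]["snapshot"])
        current = self.db.get(kind, system_id)
        record = dict(snapshot, kind=kind, pk=current["pk"], system_id=system_id)
        self.db.replace(record)
        self.db.append_audit(kind, system_id, actor, record)
        return record

    # ---------------------------------------------------------------- queries

    def query(self, kind: str, filters: dict[str, Any] | None = None
              ) -> list[dict]:
        """Filter records by dotted-path lookups (equality or membership).

        A key like ``"technique.name"`` traverses reference fields; a key
        suffix ``"__in"`` tests membership of the leaf value in the given
        collection.  Records are returned ordered by system_id.
        """
        if kind not in schema.SCHEMAS:
            raise FilterError(f"unknown entity kind {kind!r}")
        filters = filters or {}
        compiled = [self._compile_filter(kind, k, v) for k, v in filters.items()]
        out = []
        for rec in self.db.all(kind):
            if all(pred(rec) for pred in compiled):
                out.append(rec)
        return out

    def _compile_filter(self, kind: str, key: str, value: Any
                        ) -> Callable[[dict], bool]:
        op = "eq"
        if key.endswith("__in"):
            op, key = "in", key[: -len("__in")]
        path = key.split(".")
        # static validation of the path against the schemas
        cur = kind
        for i, step in enumerate(path):
            specs = schema.fields_of(cur)
            exts = self.extensions_for(cur) if cur in schema.EXTENSIBLE_KINDS else {}
            if step in specs:
                spec = specs[step]
                if spec.ref and i < len(path) - 1:
                    cur = spec.ref
                elif i < len(path) - 1:
                    raise FilterError(f"cannot traverse non-reference field {step!r}")
            elif step in exts:
                if i < len(path) - 1:
                    raise FilterError(f"cannot traverse custom field {step!r}")
            else:
                raise FilterError(f"unknown field {step!r} on kind {cur!r}")

        def leaves(rec: dict, k: str, steps: list[str]) -> Iterable[Any]:
            if not steps:
                yield rec
                return
            step, rest = steps[0], steps[1:]
            spec = schema.fields_of(k).get(step)
            if spec is None:  # declared custom field
                yield rec.get("custom_fields", {}).get(step)
                return
            value = rec.get(step)
            if spec.ref:
                ids = value if spec.many else ([value] if value else [])
                for sid in ids or []:
                    sub = self.db.find(sid)
                    if sub is None:
                        continue
                    if rest:
                        yield from leaves(sub, spec.ref, rest)
                    else:
                        yield sid
            else:
                yield value

        def matches(rec: dict) -> bool:
            for leaf in leaves(rec, kind, path):
                if op == "in":
                    if leaf in value:
                        return True
                elif leaf == value or (leaf is not None and str(leaf) == str(value)):
                    return True
            return False

        return matches

    # ------------------------------------------------------ batch registration

    def batch_register(self, table_path: str | Path, project: dict,
                       actor: str = "admin") -> BatchReport:
        """Register one experiment per row, reusing individuals/samples.

        Rows are processed independently; a bad row is rejected (with its
        index and reason) without blocking the rest of the file.
        """
        frame = self._read_table(Path(table_path))
        report = BatchReport()
        for idx, row in frame.iterrows():
            try:
                with self.db.transaction():
                    experiment = self._register_row(row, project, actor)
                report.created.append(experiment)
            except Exception as exc:  # per-row atomicity: reject and move on
                report.rejected.append((int(idx), str(exc)))
        return report

    def _read_table(self, path: Path) -> pd.DataFrame:
        if not path.exists():
            raise FormatError(f"batch table {path} does not exist")
        try:
            if path.suffix.lower() in (".xlsx", ".xls"):
                frame = pd.read_excel(path, sheet_name=0, dtype=object)
            elif path.suffix.lower() == ".csv":
                frame = pd.read_csv(path, dtype=object)
            else:
                frame = pd.read_csv(path, sep="\t", dtype=object)
        except FormatError:
            raise
        except Exception as exc:
            raise FormatError(f"unreadable batch table {path}: {exc}") from exc
        frame.columns = [str(c).strip().lower() for c in frame.columns]
        missing = [c for c in BATCH_MANDATORY if c not in frame.columns]
        if missing:
            raise FormatError(f"batch table missing mandatory columns: {missing}")
        return frame

    @staticmethod
    def _cell(row: pd.Series, column: str) -> str | None:
        if column not in row.index:
            return None
        value = row[column]
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        text = str(value).strip()
        return text or None

    def _register_row(self, row: pd.Series, project: dict, actor: str) -> dict:
        values = {c: self._cell(row, c) for c in row.index}
        for column in BATCH_MANDATORY:
            if not values.get(column):
                raise ValidationError(f"missing value for column {column!r}")

        extras: dict[str, dict[str, Any]] = {"individual": {}, "sample": {},
                                             "experiment": {}}
        known = set(BATCH_MANDATORY) | set(BATCH_OPTIONAL)
        for column, value in values.items():
            if column in known or value is None:
                continue
            owner = next((k for k in ("experiment", "sample", "individual")
                          if column in self.extensions_for(k)), None)
            if owner is None:
                raise ValidationError(f"undeclared extra column {column!r}")
            ext = self.extensions_for(owner)[column]
            extras[owner][column] = _coerce_scalar(value, ext["value_type"])

        technique = self._get_or_create(
            "technique",
            {"name": values["technique"],
             "category": values.get("technique_category") or "DNA"},
            match=("name",), actor=actor)
        platform = self._get_or_create(
            "platform", {"manufacturer": "GENERIC", "model": values["platform"]},
            match=("model",), actor=actor)
        individual = self._get_or_create(
            "individual",
            {"custom_id": values["individual_id"], "species": values["species"],
             "center": values["center"], "sex": values.get("sex") or "UNKNOWN",
             "custom_fields": extras["individual"]},
            match=("custom_id", "center", "species"), actor=actor)

        sample = next((s for s in self.db.all("sample")
                       if s["custom_id"] == values["sample_id"]), None)
        if sample is None:
            sample = self.create_record("sample", {
                "custom_id": values["sample_id"],
                "individual": individual["system_id"],
                "sample_class": values.get("sample_class") or "OTHER",
                "collection_state": values.get("collection_state"),
                "custom_fields": extras["sample"],
            }, actor=actor)
        elif sample["individual"] != individual["system_id"]:
            raise ValidationError(
                f"sample {values['sample_id']!r} already belongs to another individual")

        if any(e["custom_id"] == values["experiment_id"]
               for e in self.db.all("experiment")):
            raise ValidationError(f"duplicate experiment {values['experiment_id']!r}")
        return self.create_record("experiment", {
            "custom_id": values["experiment_id"],
            "sample": sample["system_id"],
            "technique": technique["system_id"],
            "platform": platform["system_id"],
            "projects": [project["system_id"]],
            "import_status": "REGISTERED",
            "custom_fields": extras["experiment"],
        }, actor=actor)

    def _get_or_create(self, kind: str, fields: dict, match: tuple[str, ...],
                       actor: str) -> dict:
        for rec in self.db.all(kind):
            if all(rec.get(f) == fields.get(f) for f in match):
                return rec
        return self.create_record(kind, fields, actor=actor)

    # -------------------------------------------------------- individual tree

    def individual_tree(self, individual_id: str) -> dict:
        """Nested view individual→samples→(aliquots)→experiments→analyses."""
        individual = self.db.get("individual", individual_id)
        analyses = [a for a in self.db.all("analysis") if not a.get("superseded")]

        def experiment_node(exp: dict) -> dict:
            children = [
                {"kind": "analysis", "record": a, "children": []}
                for a in analyses if exp["system_id"] in a.get("targets", [])
            ]
            return {"kind": "experiment", "record": exp, "children": children}

        def sample_node(smp: dict) -> dict:
            children: list[dict] = []
            for alq in self.db.all("aliquot"):
                if alq["sample"] != smp["system_id"]:
                    continue
                exps = [e for e in self.db.all("experiment")
                        if e.get("aliquot") == alq["system_id"]]
                children.append({"kind": "aliquot", "record": alq,
                                 "children": [experiment_node(e) for e in exps]})
            for exp in self.db.all("experiment"):
                if exp["sample"] == smp["system_id"] and not exp.get("aliquot"):
                    children.append(experiment_node(exp))
            return {"kind": "sample", "record": smp, "children": children}

        samples = [s for s in self.db.all("sample")
                   if s["individual"] == individual_id]
        return {"kind": "individual", "record": individual,
                "children": [sample_node(s) for s in samples]}


def _coerce_scalar(value: str, value_type: str) -> Any:
    if value_type == "number":
        try:
            num = float(value)
        except ValueError as exc:
            raise ValidationError(f"{value!r} is not a number") from exc
        return int(num) if num == int(num) else num
    if value_type == "boolean":
        low = value.lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise ValidationError(f"{value!r} is not a boolean")
    return value
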