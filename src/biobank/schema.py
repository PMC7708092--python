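"""Declarative field schemas for every entity kind.

Built-in fields are fixed here; per-deployment custom fields are added at
run time through schema-extension records (see
:meth:`biobank.metadata.MetadataStore.register_extension`) and validated with
the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

#: value types permitted for custom fields and scalar analysis results
SCALAR_TYPES = {"number", "boolean", "text"}

SEXES = {"MALE", "FEMALE", "UNKNOWN"}
SAMPLE_CLASSES = {"TUMOR", "NORMAL", "METASTASIS", "CELL_LINE", "OTHER"}
TECHNIQUE_CATEGORIES = {"DNA", "RNA", "IMAGE", "OTHER"}
IMPORT_STATUSES = {"UNREGISTERED", "REGISTERED", "IMPORTED"}
ANALYSIS_STATUSES = {"CREATED", "STAGED", "SUBMITTED", "STARTED", "SUCCEEDED", "FAILED"}
ROLES = {"MANAGER", "ANALYST", "ENGINEER"}
FILE_TYPES = {"FASTQ_R1", "FASTQ_R2", "BAM", "CRAM", "IMAGE", "TABLE", "OTHER"}


@dataclass(frozen=True)
class Field:
    name: str
    type: str = "text"              # text | number | boolean | map | list
    required: bool = False
    ref: str | None = None          # target kind for reference fields
    many: bool = False              # list of references / values
    immutable: bool = False
    choices: frozenset[str] | None = None
    default: Any = None


def _f(name, **kw):
    if "choices" in kw and kw["choices"] is not None:
        kw["choices"] = frozenset(kw["choices"])
    return Field(name, **kw)


_COMMON = [
    _f("system_id", immutable=True),
    _f("custom_fields", type="map", default=dict),
]

SCHEMAS: dict[str, list[Field]] = {
    "individual": _COMMON + [
        _f("custom_id"),
        _f("species", required=True),
        _f("sex", choices=SEXES, default="UNKNOWN"),
        _f("center", required=True),
    ],
    "sample": _COMMON + [
        _f("custom_id"),
        _f("individual", ref="individual", required=True),
        _f("sample_class", choices=SAMPLE_CLASSES, default="OTHER"),
        _f("disease", ref="disease"),
        _f("collection_state"),
    ],
    "aliquot": _COMMON + [
        _f("custom_id"),
        _f("sample", ref="sample", required=True),
    ],
    "experiment": _COMMON + [
        _f("custom_id"),
        _f("sample", ref="sample", required=True),
        _f("aliquot", ref="aliquot"),
        _f("technique", ref="technique", required=True),
        _f("platform", ref="platform", required=True),
        _f("projects", ref="project", many=True, required=True),
        _f("raw_data", ref="data_asset", many=True, default=list),
        _f("import_status", choices=IMPORT_STATUSES, default="UNREGISTERED"),
    ],
    "project": [
        _f("system_id", immutable=True),
        _f("title", required=True),
        _f("description", default=""),
        _f("stakeholders", type="list", default=list),
        _f("creation_time", type="number"),
    ],
    "technique": [
        _f("system_id", immutable=True),
        _f("name", required=True),
        _f("category", choices=TECHNIQUE_CATEGORIES, required=True),
        _f("reference_data", type="map", default=dict),
    ],
    "platform": [
        _f("system_id", immutable=True),
        _f("manufacturer", required=True),
        _f("model", required=True),
    ],
    "disease": _COMMON + [
        _f("name", required=True),
        _f("ontology_code"),
    ],
    "user": [
        _f("system_id", immutable=True),
        _f("username", required=True),
        _f("email", default=""),
        _f("roles", type="list", default=list),
        _f("is_admin", type="boolean", default=False),
        _f("overrides", type="list", default=list),
    ],
    "data_asset": [
        _f("system_id", immutable=True),
        _f("experiment", ref="experiment", required=True),
        _f("source_path", required=True),
        _f("lake_path", required=True),
        _f("file_type", choices=FILE_TYPES, required=True),
        _f("checksum", required=True),
        _f("size", type="number", required=True),
    ],
    "reference_asset": [
        _f("system_id", immutable=True),
        _f("scope", required=True),
        _f("key", required=True),
        _f("lake_path", required=True),
        _f("checksum", required=True),
    ],
    "analysis": [
        _f("system_id", immutable=True),
        _f("application", type="map", required=True),   # identity: name/version/assembly
        _f("targets", ref="experiment", many=True, required=True),
        _f("references", ref="experiment", many=True, default=list),
        _f("projects", ref="project", many=True, default=list),
        _f("individuals", ref="individual", many=True, default=list),
        _f("status", choices=ANALYSIS_STATUSES, default="CREATED"),
        _f("storage_url", default=""),
        _f("results", type="map", default=dict),
        _f("config_snapshot", type="map", default=dict),
        _f("wall_time", type="number"),
        _f("individual_level", type="boolean", default=False),
        _f("project_level", type="boolean", default=False),
        _f("superseded", type="boolean", default=False),
        _f("superseded_at"),
    ],
    "application": [
        _f("system_id", immutable=True),
        _f("name", required=True),
        _f("version", required=True),
        _f("assembly"),
        _f("species", default=""),
        _f("settings", type="map", default=dict),
        _f("results_keys", type="list", default=list),
    ],
    "schema_extension": [
        _f("system_id", immutable=True),
        _f("entity_kind", required=True),
        _f("field_name", required=True),
        _f("value_type", choices=frozenset(SCALAR_TYPES), required=True),
        _f("required", type="boolean", default=False),
    ],
}

#: uniqueness constraints as tuples of field names, per kind
UNIQUE_TOGETHER: dict[str, tuple[str, ...]] = {
    "individual": ("center", "species", "custom_id"),
    "sample": ("custom_id",),
    "aliquot": ("custom_id",),
    "experiment": ("custom_id",),
    "technique": ("name", "category"),
    "platform": ("manufacturer", "model"),
    "disease": ("name",),
    "user": ("username",),
    "reference_asset": ("scope", "key"),
    "schema_extension": ("entity_kind", "field_name"),
}

#: kinds whose schema accepts registered custom fields
EXTENSIBLE_KINDS = {"individual", "sample", "aliquot", "experiment", "disease"}

#: kinds protected by the metadata-registration permission
METADATA_KINDS = {
    "individual", "sample", "aliquot", "experiment", "project",
    "technique", "platform", "disease",
}

#: default custom-id prefixes for the identifier template
ID_PREFIXES = {
    "individual": "I",
    "sample": "S",
    "aliquot": "A",
    "experiment": "E",
    "project": "P",
}


def fields_of(kind: str) -> dict[str, Field]:
    return {f.name: f for f in SCHEMAS[kind]}


def reference_fields() -> list[tuple[str, Field]]:
    """All (kind, field) pairs holding references — used for delete protection."""
    out = []
    for kind, specs in SCHEMAS.items():
        for f in specs:
            if f.ref:
                out.append((kind, f))
    return out


def check_scalar(value: Any, value_type: str) -> bool:
    if value_type == "number":
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if value_type == "boolean":
        return isinstance(value, bool)
    if value_type == "text":
        return isinstance(value, str)
    return False
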