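"""Checksummed, write-locked data lake.

Raw files deposited by a sequencing core (or any instrument) are matched to
registered experiments by filename, then moved or symlinked into a sharded
canonical layout under the lake root.  Every import records a SHA-256
checksum and byte size, removes write permission bits, flips the
experiment's import status (firing any registered status signals), and never
leaves a partially-registered asset behind.
"""

from __future__ import annotations

import hashlib
import os
import re
import shutil
import stat
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from .errors import (
    AlreadyImportedError,
    AmbiguityError,
    ChecksumError,
    DuplicateKeyError,
    NotFoundError,
    PermissionDenied,
)
from .metadata import MetadataStore

#: default filename patterns per file type (first match wins uniqueness check)
DEFAULT_PATTERNS: dict[str, str] = {
    "FASTQ_R1": r"_R1(_\d+)?\.f(ast)?q(\.gz)?$",
    "FASTQ_R2": r"_R2(_\d+)?\.f(ast)?q(\.gz)?$",
    "BAM": r"\.bam$",
    "CRAM": r"\.cram$",
    "IMAGE": r"\.(png|jpg|jpeg|tiff?|svs)$",
    "TABLE": r"\.(csv|tsv|txt)$",
}


@dataclass
class StorageConfig:
    lake_root: Path
    import_mode: str = "MOVE"  # MOVE | SYMLINK

    def __post_init__(self):
        # absolute: storage paths are embedded in commands run from other cwds
        self.lake_root = Path(self.lake_root).resolve()
        if self.import_mode not in ("MOVE", "SYMLINK"):
            raise ValueError(f"import_mode must be MOVE or SYMLINK, "
                             f"got {self.import_mode!r}")


@dataclass
class ScanResult:
    matches: dict[str, list[tuple[Path, str]]] = field(default_factory=dict)
    unmatched: list[tuple[Path, str]] = field(default_factory=list)


def storage_path(kind: str, numeric_key: int, config: StorageConfig) -> Path:
    """Deterministic sharded path ``<root>/<kind>/<AA>/<BB>/<key zero-padded>``.

    The two shard levels are the first and second digit pairs of the
    zero-padded key, bounding directory fan-out to 100 entries per level.
    Creates no directories.
    """
    if numeric_key < 1:
        raise ValueError("numeric_key must be >= 1")
    padded = str(numeric_key).zfill(6)
    if len(padded) % 2:
        padded = "0" + padded
    return config.lake_root / kind / padded[0:2] / padded[2:4] / padded


class DataLake:
    """Import raw and reference data for a metadata store."""

    def __init__(self, store: MetadataStore, config: StorageConfig,
                 dispatch: Callable[[dict, str, str], object] | None = None):
        self.store = store
        self.config = config
        self.dispatch = dispatch  # automations hook: (record, old, new)

    # ------------------------------------------------------------- scanning

    def scan_and_match(self, deposit_dir: str | Path, experiments: list[dict],
                       patterns: dict[str, str] | None = None) -> ScanResult:
        """Match deposited files to experiments by custom_id substring.

        A file belongs to an experiment iff its name contains that
        experiment's custom_id and matches exactly one file-type pattern.
        A file whose name contains two different experiment IDs aborts the
        whole scan: guessing would corrupt provenance.
        """
        patterns = patterns or DEFAULT_PATTERNS
        compiled = {t: re.compile(p, re.IGNORECASE) for t, p in patterns.items()}
        result = ScanResult()
        deposit_dir = Path(deposit_dir)
        for path in sorted(p for p in deposit_dir.rglob("*") if p.is_file()):
            owners = [e for e in experiments if e["custom_id"] in path.name]
            if len(owners) > 1:
                ids = [e["custom_id"] for e in owners]
                raise AmbiguityError(
                    f"file {path.name!r} matches multiple experiments {ids}")
            if not owners:
                result.unmatched.append((path, "no experiment custom_id in name"))
                continue
            types = [t for t, rx in compiled.items() if rx.search(path.name)]
            if len(types) != 1:
                reason = ("no file-type pattern" if not types
                          else f"ambiguous file types {types}")
                result.unmatched.append((path, reason))
                continue
            result.matches.setdefault(owners[0]["system_id"], []).append(
                (path, types[0]))
        return result

    # -------------------------------------------------------------- import

    def import_data(self, scan: ScanResult | dict, actor: str) -> list[dict]:
        """Relocate matched files into the lake and register DataAssets.

        Files are staged (copy + checksum verify + rename) before anything is
        registered, so a read failure mid-copy leaves no partial asset; in
        MOVE mode the source is removed only after the lake copy verifies.
        """
        self._require_admin(actor, "IMPORT_DATA")
        matches = scan.matches if isinstance(scan, ScanResult) else scan
        assets: list[dict] = []
        for exp_id, files in sorted(matches.items()):
            experiment = self.store.db.get("experiment", exp_id)
            if experiment["import_status"] == "IMPORTED":
                raise AlreadyImportedError(
                    f"experiment {experiment['custom_id']} already imported")
            raw_dir = storage_path("experiments", experiment["pk"],
                                   self.config) / "raw"
            raw_dir.mkdir(parents=True, exist_ok=True)
            exp_assets = []
            for source, file_type in sorted(files):
                dest = raw_dir / source.name
                checksum, size = self._place(Path(source), dest)
                exp_assets.append(self.store.create_record("data_asset", {
                    "experiment": exp_id,
                    "source_path": str(source),
                    "lake_path": str(dest),
                    "file_type": file_type,
                    "checksum": checksum,
                    "size": size,
                }, actor=actor))
            old = experiment["import_status"]
            experiment = self.store.update_record("experiment", exp_id, {
                "raw_data": [a["system_id"] for a in exp_assets],
                "import_status": "IMPORTED",
            }, actor=actor)
            if self.dispatch is not None:
                self.dispatch(experiment, old, "IMPORTED")
            assets.extend(exp_assets)
        return assets

    def _place(self, source: Path, dest: Path) -> tuple[str, int]:
        if not source.exists():
            raise ChecksumError(f"source file {source} disappeared")
        src_sum = sha256_file(source)
        if self.config.import_mode == "SYMLINK":
            if dest.is_symlink() or dest.exists():
                dest.unlink()
            dest.symlink_to(source.resolve())
            lock_path(source)
            return src_sum, source.stat().st_size
        tmp = dest.with_suffix(dest.suffix + ".importing")
        shutil.copy2(source, tmp)
        if sha256_file(tmp) != src_sum:
            tmp.unlink(missing_ok=True)
            raise ChecksumError(f"checksum mismatch copying {source}")
        tmp.rename(dest)
        lock_path(dest)
        source.unlink()  # MOVE: source removed only after lake copy verified
        return src_sum, dest.stat().st_size

    # ----------------------------------------------------- reference assets

    def register_reference(self, scope: str, key: str,
                           source_path: str | Path, actor: str) -> dict:
        """Register an auxiliary asset (genome FASTA, BED file, ...) by
        (scope, key); re-registration requires a distinct key."""
        self._require_admin(actor, "IMPORT_DATA")
        source = Path(source_path)
        if not source.exists():
            raise NotFoundError(f"reference source {source} does not exist")
        for rec in self.store.db.all("reference_asset"):
            if rec["scope"] == scope and rec["key"] == key:
                raise DuplicateKeyError(f"reference ({scope!r}, {key!r}) "
                                        f"already registered")
        dest_dir = self.config.lake_root / "references" / scope
        dest_dir.mkdir(parents=True, exist_ok=True)
        dest = dest_dir / source.name
        shutil.copy2(source, dest)
        checksum = sha256_file(dest)
        if checksum != sha256_file(source):
            dest.unlink(missing_ok=True)
            raise ChecksumError(f"checksum mismatch copying {source}")
        lock_path(dest)
        return self.store.create_record("reference_asset", {
            "scope": scope, "key": key, "lake_path": str(dest),
            "checksum": checksum,
        }, actor=actor)

    def get_reference(self, scope: str, key: str) -> dict:
        for rec in self.store.db.all("reference_asset"):
            if rec["scope"] == scope and rec["key"] == key:
                return rec
        raise NotFoundError(f"no reference asset ({scope!r}, {key!r})")

    def references_for(self, scope: str) -> dict[str, dict]:
        return {r["key"]: r for r in self.store.db.all("reference_asset")
                if r["scope"] == scope}

    # --------------------------------------------------------------- usage

    def storage_usage(self, record: dict) -> int:
        """Recursive byte total of the record's lake directory (0 if absent)."""
        kind = {"experiment": "experiments", "analysis": "analyses"}.get(
            record["kind"], record["kind"])
        root = storage_path(kind, record["pk"], self.config)
        if not root.exists():
            return 0
        return sum(p.stat().st_size for p in root.rglob("*") if p.is_file())

    # -------------------------------------------------------------- helpers

    def _require_admin(self, actor: str, action: str) -> None:
        if not self.store.enforce_permissions:
            return
        try:
            self.store.check_permission(actor, action)
        except PermissionDenied:
            raise


def sha256_file(path: Path, chunk: int = 1 << 20) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        while True:
            block = handle.read(chunk)
            if not block:
                break
            digest.update(block)
    return digest.hexdigest()


def lock_path(path: Path) -> None:
    """Clear all write permission bits (post-import immutability)."""
    mode = path.stat().st_mode
    path.chmod(mode & ~(stat.S_IWUSR | stat.S_IWGRP | stat.S_IWOTH))


def unlock_path(path: Path) -> None:
    path.chmod(path.stat().st_mode | stat.S_IWUSR)


def lock_tree(root: Path) -> None:
    for p in sorted(root.rglob("*"), reverse=True):
        if p.is_file() and not p.is_symlink():
            lock_path(p)
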