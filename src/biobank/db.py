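"""Embedded relational persistence on stdlib sqlite3.

Records are stored one row per entity with the field map serialized as JSON;
uniqueness, typing and referential integrity live in the application layer
(:mod:`biobank.metadata`), which keeps custom-field extensions cheap.  The
audit table is append-only: rows are inserted, never updated or deleted, and
survive deletion of the record they snapshot.
"""

from __future__ import annotations

import json
import sqlite3
import time
import uuid
from contextlib import contextmanager
from typing import Any, Iterator

from .errors import NotFoundError

_SCHEMA = """
CREATE TABLE IF NOT EXISTS records (
    kind      TEXT NOT NULL,
    pk        INTEGER NOT NULL,
    system_id TEXT NOT NULL UNIQUE,
    data      TEXT NOT NULL,
    PRIMARY KEY (kind, pk)
);
CREATE TABLE IF NOT EXISTS audit (
    kind      TEXT NOT NULL,
    entity_id TEXT NOT NULL,
    version   INTEGER NOT NULL,
    timestamp REAL NOT NULL,
    actor     TEXT NOT NULL,
    snapshot  TEXT NOT NULL,
    PRIMARY KEY (kind, entity_id, version)
);
CREATE TABLE IF NOT EXISTS counters (
    name  TEXT PRIMARY KEY,
    value INTEGER NOT NULL
);
CREATE INDEX IF NOT EXISTS idx_records_kind ON records (kind);
CREATE INDEX IF NOT EXISTS idx_audit_entity ON audit (kind, entity_id);
"""


class Database:
    """Thin record/audit store over a single sqlite file (or ``:memory:``)."""

    def __init__(self, path: str = ":memory:"):
        self.path = str(path)
        # cross-thread use is safe: sqlite3 here is built with serialized
        # threading, and writers coordinate via advisory locks upstream
        self._conn = sqlite3.connect(self.path, isolation_level=None,
                                     check_same_thread=False)
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._conn.executescript(_SCHEMA)

    def close(self) -> None:
        self._conn.close()

    # -- transactions -------------------------------------------------------

    @contextmanager
    def transaction(self) -> Iterator[None]:
        """Savepoint-scoped atomicity (used for per-row batch registration)."""
        name = f"sp_{uuid.uuid4().hex[:8]}"
        self._conn.execute(f"SAVEPOINT {name}")
        try:
            yield
        except BaseException:
            self._conn.execute(f"ROLLBACK TO SAVEPOINT {name}")
            self._conn.execute(f"RELEASE SAVEPOINT {name}")
            raise
        else:
            self._conn.execute(f"RELEASE SAVEPOINT {name}")

    # -- counters -----------------------------------------------------------

    def next_counter(self, name: str) -> int:
        cur = self._conn.execute(
            "INSERT INTO counters (name, value) VALUES (?, 1) "
            "ON CONFLICT(name) DO UPDATE SET value = value + 1 "
            "RETURNING value",
            (name,),
        )
        (value,) = cur.fetchone()
        return int(value)

    # -- records ------------------------------------------------------------

    def insert(self, kind: str, data: dict[str, Any]) -> dict[str, Any]:
        """Persist a new record; assigns ``pk`` (per-kind) and ``system_id``."""
        pk = self.next_counter(f"pk:{kind}")
        system_id = data.get("system_id") or str(uuid.uuid4())
        record = dict(data, kind=kind, pk=pk, system_id=system_id)
        self._conn.execute(
            "INSERT INTO records (kind, pk, system_id, data) VALUES (?,?,?,?)",
            (kind, pk, system_id, json.dumps(record, sort_keys=True)),
        )
        return record

    def replace(self, record: dict[str, Any]) -> dict[str, Any]:
        self._conn.execute(
            "UPDATE records SET data = ? WHERE system_id = ?",
            (json.dumps(record, sort_keys=True), record["system_id"]),
        )
        return record

    def get(self, kind: str, system_id: str) -> dict[str, Any]:
        row = self._conn.execute(
            "SELECT data FROM records WHERE kind = ? AND system_id = ?",
            (kind, system_id),
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no {kind} with system_id {system_id!r}")
        return json.loads(row[0])

    def find(self, system_id: str) -> dict[str, Any] | None:
        """Look up a record by system_id across all kinds."""
        row = self._conn.execute(
            "SELECT data FROM records WHERE system_id = ?", (system_id,)
        ).fetchone()
        return None if row is None else json.loads(row[0])

    def exists(self, kind: str, system_id: str) -> bool:
        row = self._conn.execute(
            "SELECT 1 FROM records WHERE kind = ? AND system_id = ?",
            (kind, system_id),
        ).fetchone()
        return row is not None

    def delete(self, kind: str, system_id: str) -> None:
        cur = self._conn.execute(
            "DELETE FROM records WHERE kind = ? AND system_id = ?",
            (kind, system_id),
        )
        if cur.rowcount == 0:
            raise NotFoundError(f"no {kind} with system_id {system_id!r}")

    def all(self, kind: str) -> list[dict[str, Any]]:
        rows = self._conn.execute(
            "SELECT data FROM records WHERE kind = ? ORDER BY system_id",
            (kind,),
        ).fetchall()
        return [json.loads(r[0]) for r in rows]

    def kinds(self) -> list[str]:
        rows = self._conn.execute("SELECT DISTINCT kind FROM records").fetchall()
        return [r[0] for r in rows]

    # -- audit trail --------------------------------------------------------

    def append_audit(
        self, kind: str, entity_id: str, actor: str, snapshot: dict[str, Any]
    ) -> dict[str, Any]:
        """Append the next audit version; timestamps are strictly increasing."""
        row = self._conn.execute(
            "SELECT MAX(version), MAX(timestamp) FROM audit "
            "WHERE kind = ? AND entity_id = ?",
            (kind, entity_id),
        ).fetchone()
        version = (row[0] or 0) + 1
        now = time.time()
        if row[1] is not None and now <= row[1]:
            now = row[1] + 1e-6
        self._conn.execute(
            "INSERT INTO audit (kind, entity_id, version, timestamp, actor, snapshot)"
            " VALUES (?,?,?,?,?,?)",
            (kind, entity_id, version, now, actor, json.dumps(snapshot, sort_keys=True)),
        )
        return {
            "entity_kind": kind,
            "entity_id": entity_id,
            "version": version,
            "timestamp": now,
            "actor": actor,
            "snapshot": snapshot,
        }

    def history(self, kind: str, entity_id: str) -> list[dict[str, Any]]:
        rows = self._conn.execute(
            "SELECT version, timestamp, actor, snapshot FROM audit "
            "WHERE kind = ? AND entity_id = ? ORDER BY version",
            (kind, entity_id),
        ).fetchall()
        return [
            {
                "entity_kind": kind,
                "entity_id": entity_id,
                "version": v,
                "timestamp": ts,
                "actor": actor,
                "snapshot": json.loads(snap),
            }
            for v, ts, actor, snap in rows
        ]
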