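"""Status-driven automations: signals, auto-merge, and scheduled tasks.

*Signals* are functions triggered on status transitions (e.g. deploy QC when
data is imported; deploy downstream apps when QC succeeds).  Signal failures
are contained — they are logged and reported through a notification hook
with restart instructions, and never corrupt the triggering record's status
or block other signals.

*Auto-merge* aggregates all SUCCEEDED analyses of one application at project
or individual scope into a single versioned output.  It is gated: a merge
runs only when at least one analysis has succeeded and none of that
application's analyses in scope are still in flight, and it is not rerun
while the succeeded set is unchanged.
"""

from __future__ import annotations

import datetime
import threading
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Callable

from .applications import NON_TERMINAL, AppRegistry, ApplicationDescriptor
from .datalake import lock_tree, storage_path
from .errors import DuplicateSignalError, MergeHookError


@dataclass
class Signal:
    name: str
    trigger: Callable[[dict, str | None, str], bool]
    action: Callable[[dict, str | None, str], Any]
    on_failure: Callable[..., None] | None = None


@dataclass
class SignalOutcome:
    signal: str
    ok: bool
    result: Any = None
    error: str = ""


class SignalRegistry:
    """Ordered signal registry; ``dispatch`` is called once per persisted
    status transition by the import and status-setting code paths."""

    def __init__(self, notifier: Callable[[str, dict, str, str], None] | None = None):
        self._signals: list[Signal] = []
        self.notifications: list[dict] = []
        self.notifier = notifier
        self.log: list[tuple[dict, str | None, str, list[SignalOutcome]]] = []

    def register(self, signal: Signal) -> None:
        if any(s.name == signal.name for s in self._signals):
            raise DuplicateSignalError(f"signal {signal.name!r} already registered")
        self._signals.append(signal)

    def unregister(self, name: str) -> None:
        self._signals = [s for s in self._signals if s.name != name]

    def dispatch(self, record: dict, old_status: str | None,
                 new_status: str) -> list[SignalOutcome]:
        """Run every matching signal in registration order; exceptions are
        caught, reported via the failure hook, and never propagated."""
        outcomes: list[SignalOutcome] = []
        for signal in list(self._signals):
            try:
                if not signal.trigger(record, old_status, new_status):
                    continue
            except Exception as exc:
                outcomes.append(self._failed(signal, record, exc))
                continue
            try:
                result = signal.action(record, old_status, new_status)
                outcomes.append(SignalOutcome(signal.name, True, result=result))
            except Exception as exc:
                outcomes.append(self._failed(signal, record, exc))
        self.log.append((record, old_status, new_status, outcomes))
        return outcomes

    def _failed(self, signal: Signal, record: dict,
                exc: Exception) -> SignalOutcome:
        message = f"{type(exc).__name__}: {exc}"
        instructions = (f"signal {signal.name!r} failed on "
                        f"{record.get('kind')} {record.get('system_id')}; "
                        f"fix the cause and re-dispatch the transition to restart")
        note = {"signal": signal.name, "record": record.get("system_id"),
                "error": message, "instructions": instructions}
        self.notifications.append(note)
        hook = signal.on_failure or self.notifier
        if hook is not None:
            try:
                hook(signal.name, record, message, instructions)
            except Exception:
                pass  # a broken notifier must not break dispatch
        return SignalOutcome(signal.name, False, error=message)


# ---------------------------------------------------------------- auto-merge

@dataclass
class MergeSpec:
    application: ApplicationDescriptor
    level: str                                   # PROJECT | INDIVIDUAL
    merge_hook: Callable[..., Any] | None = None

    def __post_init__(self):
        if self.level not in ("PROJECT", "INDIVIDUAL"):
            raise ValueError(f"level must be PROJECT or INDIVIDUAL, "
                             f"got {self.level!r}")
        if self.merge_hook is None:
            self.merge_hook = (self.application.merge_project
                               if self.level == "PROJECT"
                               else self.application.merge_individual)


class AutoMerger:
    """Evaluates and executes gated merges over an :class:`AppRegistry`."""

    def __init__(self, apps: AppRegistry):
        self.apps = apps
        self._locks: dict[tuple, threading.Lock] = {}
        self._locks_guard = threading.Lock()
        self.executed: list[dict] = []   # event log for gating audits

    # -- census --------------------------------------------------------

    def _scope_analyses(self, spec: MergeSpec, scope_record: dict) -> list[dict]:
        scope_field = "projects" if spec.level == "PROJECT" else "individuals"
        return [
            rec for rec in self.apps.store.db.all("analysis")
            if not rec.get("superseded")
            and not rec.get("project_level") and not rec.get("individual_level")
            and rec["application"] == spec.application.identity_map
            and scope_record["system_id"] in rec.get(scope_field, [])
        ]

    def should_merge(self, spec: MergeSpec, scope_record: dict) -> bool:
        """True iff ≥1 SUCCEEDED analysis of the application exists in scope
        and none of its analyses in scope are still non-terminal."""
        statuses = [rec["status"] for rec in self._scope_analyses(spec, scope_record)]
        if not any(s == "SUCCEEDED" for s in statuses):
            return False
        return not any(s in NON_TERMINAL for s in statuses)

    def _previous_merge(self, spec: MergeSpec, scope_record: dict) -> dict | None:
        flag = "project_level" if spec.level == "PROJECT" else "individual_level"
        scope_field = "projects" if spec.level == "PROJECT" else "individuals"
        for rec in self.apps.store.db.all("analysis"):
            if (not rec.get("superseded") and rec.get(flag)
                    and rec["application"] == spec.application.identity_map
                    and rec.get(scope_field) == [scope_record["system_id"]]):
                return rec
        return None

    # -- execution -----------------------------------------------------

    def run_merge(self, spec: MergeSpec, scope_record: dict) -> dict | None:
        """Merge all SUCCEEDED analyses in scope into one versioned output.

        No-ops (returning the previous merge or None) when the gate does not
        hold, when the succeeded set is unchanged since the last merge, or
        when another merge for the same scope is already in flight.
        """
        key = (spec.application.identity, spec.level, scope_record["system_id"])
        with self._locks_guard:
            lock = self._locks.setdefault(key, threading.Lock())
        if not lock.acquire(blocking=False):
            return None  # concurrent merge in flight for this scope: no-op
        try:
            if not self.should_merge(spec, scope_record):
                return None
            inputs = sorted(self._scope_analyses(spec, scope_record),
                            key=lambda r: r["pk"])
            succeeded = [r for r in inputs if r["status"] == "SUCCEEDED"]
            input_ids = [r["system_id"] for r in succeeded]
            previous = self._previous_merge(spec, scope_record)
            if previous is not None and \
                    previous["config_snapshot"].get("merged_inputs") == input_ids:
                return previous  # quiescent: succeeded set unchanged
            return self._execute(spec, scope_record, succeeded, previous)
        finally:
            lock.release()

    def _execute(self, spec: MergeSpec, scope_record: dict,
                 succeeded: list[dict], previous: dict | None) -> dict:
        store = self.apps.store
        app = spec.application
        flag = "project_level" if spec.level == "PROJECT" else "individual_level"
        scope_field = "projects" if spec.level == "PROJECT" else "individuals"
        scope_kind = "projects" if spec.level == "PROJECT" else "individuals"
        targets = sorted({t for rec in succeeded for t in rec["targets"]})
        analysis = store.create_record("analysis", {
            "application": app.identity_map,
            "targets": targets,
            "references": [],
            scope_field: [scope_record["system_id"]],
            "status": "CREATED",
            flag: True,
            "config_snapshot": {
                "application": app.identity_map,
                "merged_inputs": [r["system_id"] for r in succeeded],
            },
        }, actor="admin")
        storage = (storage_path(scope_kind, scope_record["pk"], self.apps.lake.config)
                   / "merged" / app.name / app.version / str(analysis["pk"]))
        storage.mkdir(parents=True, exist_ok=True)
        (storage / "results").mkdir(exist_ok=True)
        analysis = store.update_record("analysis", analysis["system_id"], {
            "storage_url": str(storage)}, actor="admin")
        # walk the lifecycle so the digraph invariant holds for merges too
        for status in ("STAGED", "SUBMITTED", "STARTED"):
            analysis = store.update_record(
                "analysis", analysis["system_id"], {"status": status},
                actor="admin")
        try:
            results = spec.merge_hook(app, succeeded, str(storage / "results"))
        except Exception as exc:
            store.update_record("analysis", analysis["system_id"],
                                {"status": "FAILED"}, actor="admin")
            raise MergeHookError(f"merge hook for {app.label} failed: {exc}") \
                from exc
        analysis = store.update_record("analysis", analysis["system_id"], {
            "status": "SUCCEEDED", "results": results or {}}, actor="admin")
        lock_tree(storage)
        if previous is not None:
            stamp = datetime.datetime.now(datetime.timezone.utc).strftime(
                "%Y-%m-%dT%H:%M:%S.%fZ")
            AppRegistry._archive(Path(previous["storage_url"]), stamp)
            store.update_record("analysis", previous["system_id"], {
                "superseded": True, "superseded_at": stamp}, actor="admin")
        self.executed.append(analysis)
        return analysis

    # -- signal wiring ---------------------------------------------------

    def make_signal(self, spec: MergeSpec, name: str | None = None) -> Signal:
        """A signal that re-evaluates the merge whenever an analysis of the
        application reaches a terminal status."""
        scope_field = "projects" if spec.level == "PROJECT" else "individuals"

        def trigger(record: dict, old: str | None, new: str) -> bool:
            return (record.get("kind") == "analysis"
                    and not record.get("project_level")
                    and not record.get("individual_level")
                    and record.get("application") == spec.application.identity_map
                    and new in ("SUCCEEDED", "FAILED"))

        def action(record: dict, old: str | None, new: str) -> list[dict]:
            merged = []
            for scope_id in record.get(scope_field, []):
                kind = "project" if spec.level == "PROJECT" else "individual"
                scope = self.apps.store.db.get(kind, scope_id)
                out = self.run_merge(spec, scope)
                if out is not None:
                    merged.append(out)
            return merged

        return Signal(name or f"auto-merge:{spec.application.label}:{spec.level}",
                      trigger, action)


# ------------------------------------------------------------------ scheduler

@dataclass
class _Task:
    period: float
    action: Callable[[], Any]
    last_run: float | None = None
    cancelled: bool = False


class Scheduler:
    """Periodic task runner driven by explicit ticks (no daemon thread).

    ``tick`` invokes each task at most once per period; a raising action is
    logged and the schedule continues.
    """

    def __init__(self):
        self._tasks: dict[int, _Task] = {}
        self._next = 1
        self.errors: list[tuple[int, str]] = []

    def schedule_task(self, period: float, action: Callable[[], Any]) -> int:
        if period <= 0:
            raise ValueError("period must be positive")
        handle = self._next
        self._next += 1
        self._tasks[handle] = _Task(period, action)
        return handle

    def cancel(self, handle: int) -> None:
        if handle in self._tasks:
            self._tasks[handle].cancelled = True

    def tick(self, now: float | None = None) -> list[int]:
        now = time.monotonic() if now is None else now
        ran = []
        for handle, task in self._tasks.items():
            if task.cancelled:
                continue
            if task.last_run is not None and now - task.last_run < task.period:
                continue
            task.last_run = now
            try:
                task.action()
            except Exception as exc:
                self.errors.append((handle, f"{type(exc).__name__}: {exc}"))
            ran.append(handle)
        return ran
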