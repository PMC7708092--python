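"""Pluggable job executors.

Applications never execute analytical logic in-process: they construct a
shell command and hand it to an executor.  The contract is asynchronous —
``submit`` returns a handle without waiting, ``poll`` reports ``running``
until the job finishes and then ``done(exit_code)`` exactly once.
"""

from __future__ import annotations

import itertools
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ExecutorError


@dataclass(frozen=True)
class JobStatus:
    state: str                 # "running" | "done"
    exit_code: int | None = None

    @property
    def done(self) -> bool:
        return self.state == "done"


RUNNING = JobStatus("running")


class LocalExecutor:
    """Run commands as local child processes (stdout/err under ``logs/``)."""

    capability = "LOCAL"

    def __init__(self):
        self._jobs: dict[int, subprocess.Popen] = {}
        self._reported: set[int] = set()
        self._ids = itertools.count(1)

    def submit(self, command: str, working_dir: str | Path,
               env: dict[str, str] | None = None) -> int:
        working_dir = Path(working_dir)
        logs = working_dir / "logs"
        logs.mkdir(parents=True, exist_ok=True)
        try:
            proc = subprocess.Popen(
                command, shell=True, cwd=working_dir,
                stdout=open(logs / "head_job.out", "w"),
                stderr=open(logs / "head_job.err", "w"),
                env=None if env is None else {**__import__("os").environ, **env},
            )
        except OSError as exc:
            raise ExecutorError(f"failed to spawn {command!r}: {exc}") from exc
        handle = next(self._ids)
        self._jobs[handle] = proc
        return handle

    def poll(self, handle: int) -> JobStatus:
        proc = self._jobs[handle]
        code = proc.poll()
        if code is None:
            return RUNNING
        if handle in self._reported:
            raise ExecutorError(f"job {handle} already reported done")
        self._reported.add(handle)
        return JobStatus("done", code)


@dataclass
class RecordingExecutor:
    """Test stub: records submissions; completes with a fixed exit code
    without executing anything."""

    capability = "LOCAL"
    exit_code: int = 0
    fail_submit: bool = False
    submitted: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self._ids = itertools.count(1)
        self._reported: set[int] = set()

    def submit(self, command: str, working_dir: str | Path,
               env: dict[str, str] | None = None) -> int:
        if self.fail_submit:
            raise ExecutorError("submission refused (stub)")
        self.submitted.append((command, str(working_dir)))
        return next(self._ids)

    def poll(self, handle: int) -> JobStatus:
        if handle in self._reported:
            raise ExecutorError(f"job {handle} already reported done")
        self._reported.add(handle)
        return JobStatus("done", self.exit_code)
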