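"""Exception hierarchy.

Every domain failure derives from :class:`BiobankError` so callers (and the
CLI) can distinguish domain errors (exit code 1) from usage bugs.
"""

from __future__ import annotations


class BiobankError(Exception):
    """Base class for all domain errors."""


class ValidationError(BiobankError):
    """A field is missing, ill-typed, unknown, or violates an invariant."""


class DanglingReferenceError(ValidationError):
    """A reference field points at a record that does not exist."""


class PermissionDenied(BiobankError):
    """The acting user is not authorized for the attempted action."""


class UnknownActionError(BiobankError):
    """An authorization check was made for an action outside the enum."""


class NotFoundError(BiobankError):
    """The addressed record does not exist (and never existed, for history)."""


class ProtectedError(BiobankError):
    """Deletion refused because other records still reference the target.

    ``protected`` lists the referencing records as ``(kind, system_id)``.
    """

    def __init__(self, message: str, protected: list[tuple[str, str]]):
        super().__init__(message)
        self.protected = protected


class VersionError(BiobankError):
    """The requested audit version does not exist."""


class FormatError(BiobankError):
    """A batch table is unreadable or lacks mandatory columns."""


class FilterError(BiobankError):
    """A query filter names an unknown field or unsupported lookup."""


class AmbiguityError(BiobankError):
    """A deposited file matches more than one experiment; scan aborted."""


class AlreadyImportedError(BiobankError):
    """The experiment already holds imported raw data."""


class ChecksumError(BiobankError):
    """Data corruption detected between source and lake copy."""


class DuplicateKeyError(BiobankError):
    """A (scope, key) reference-asset pair is already registered."""


class DuplicateApplicationError(BiobankError):
    """The (name, version, assembly) identity is already registered."""


class DuplicateSignalError(BiobankError):
    """A signal with this name is already registered."""


class DesignError(BiobankError):
    """An experimental-design plan is missing required labels or pool."""


class NotImportedError(BiobankError):
    """An analysis was requested on experiments without imported data."""


class TupleRejectedError(BiobankError):
    """The application's validation hook rejected the experiment tuple."""


class IllegalTransitionError(BiobankError):
    """The analysis status transition is not in the lifecycle digraph."""


class VersionOrderError(BiobankError):
    """Supersession requires a strictly newer application version."""


class NotReadyError(BiobankError):
    """Results were requested from an analysis that has not succeeded."""


class UnknownResultError(BiobankError):
    """The result key is not declared in the application's results spec."""


class ExecutorError(BiobankError):
    """Job submission through the executor failed."""


class MergeHookError(BiobankError):
    """The application's merge hook raised; merge analysis marked FAILED."""
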