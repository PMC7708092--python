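"""Role-based authorization.

Three additive roles gate the two main verbs — MANAGER registers metadata,
ANALYST runs analyses, ENGINEER does both — while data import is reserved to
the single admin data-owner account.  Per-user overrides can extend (never
revoke) grants.  Authorization is a pure function of (roles, overrides,
admin flag, action), so repeated calls always agree.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import NotFoundError, PermissionDenied, UnknownActionError

ACTIONS = ("REGISTER_METADATA", "RUN_ANALYSIS", "IMPORT_DATA", "EDIT_PROJECT")

ROLE_GRANTS: dict[str, frozenset[str]] = {
    "MANAGER": frozenset({"REGISTER_METADATA"}),
    "ANALYST": frozenset({"RUN_ANALYSIS"}),
    "ENGINEER": frozenset({"REGISTER_METADATA", "RUN_ANALYSIS", "EDIT_PROJECT"}),
}


@dataclass(frozen=True)
class Decision:
    allowed: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.allowed


def authorize(user: dict, action: str, project: dict | None = None) -> Decision:
    """Decide whether ``user`` (a user record) may perform ``action``.

    ``project`` is consulted only for EDIT_PROJECT, which is granted to the
    project's stakeholders in addition to engineers and the admin.
    """
    if action not in ACTIONS:
        raise UnknownActionError(f"unknown action {action!r}")
    username = user.get("username", "?")
    if user.get("is_admin"):
        return Decision(True, "admin account")
    if action in (user.get("overrides") or []):
        return Decision(True, "per-user override")
    granted: set[str] = set()
    for role in user.get("roles") or []:
        granted |= ROLE_GRANTS.get(role, frozenset())
    if action == "IMPORT_DATA":
        return Decision(False, f"data import is limited to the admin account "
                               f"({username} is not admin)")
    if action == "EDIT_PROJECT" and project is not None:
        if username in (project.get("stakeholders") or []):
            return Decision(True, "project stakeholder")
    if action in granted:
        return Decision(True, f"granted by roles {sorted(user.get('roles') or [])}")
    return Decision(False, f"{username} (roles {sorted(user.get('roles') or [])}) "
                           f"lacks {action}")


def grant_override(store, username: str, action: str, actor: str) -> dict:
    """Grant a single action to a user irrespective of roles (admin only).

    The change goes through the metadata store so it is audited; granting an
    action twice is idempotent.
    """
    if action not in ACTIONS:
        raise UnknownActionError(f"unknown action {action!r}")
    try:
        admin = store.get_user(actor)
    except NotFoundError:
        raise PermissionDenied(f"unknown actor {actor!r}") from None
    if not admin.get("is_admin"):
        raise PermissionDenied(f"{actor} is not the admin account")
    user = store.get_user(username)
    overrides = sorted(set(user.get("overrides") or []) | {action})
    return store.update_record("user", user["system_id"],
                               {"overrides": overrides}, actor=actor)
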