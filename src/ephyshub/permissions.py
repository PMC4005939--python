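"""Per-object access control.

Every object is born private: only its owner can see it.  The owner can
grant read or read-write access to individual users, or open the object to
everyone by setting the safety level to public.  Read-write always implies
read.  ACLs are administrative state and live beside the version history,
not inside it.
"""

from __future__ import annotations

import secrets
from dataclasses import dataclass, field
from typing import Optional

from .errors import BadRequest

ACCESS_NONE = "none"
ACCESS_READ = "read"
ACCESS_READ_WRITE = "read-write"

_ACCESS_RANK = {ACCESS_NONE: 0, ACCESS_READ: 1, ACCESS_READ_WRITE: 2}

SAFETY_LEVELS = ("private", "public")
SHARE_LEVELS = (ACCESS_READ, ACCESS_READ_WRITE)


@dataclass
class ACL:
    """Safety level plus per-user access map for one object."""

    owner: str
    safety_level: str = "private"
    shared_with: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.safety_level not in SAFETY_LEVELS:
            raise BadRequest(f"invalid safety level {self.safety_level!r}")
        for user, level in self.shared_with.items():
            if level not in SHARE_LEVELS:
                raise BadRequest(f"invalid access level {level!r} for {user!r}")
        # the owner's access is implicit and cannot be shadowed by a share
        self.shared_with.pop(self.owner, None)

    def to_json(self) -> dict:
        return {
            "safety_level": self.safety_level,
            "shared_with": dict(self.shared_with),
        }


def effective_access(acl: ACL, actor: Optional[str]) -> str:
    """Resolve what ``actor`` may do with an object guarded by ``acl``.

    The owner always has read-write access; listed users get their granted
    level; on public objects everyone else still gets read.
    """
    if actor is not None and actor == acl.owner:
        return ACCESS_READ_WRITE
    granted = acl.shared_with.get(actor, ACCESS_NONE) if actor else ACCESS_NONE
    if acl.safety_level == "public":
        return max(granted, ACCESS_READ, key=_ACCESS_RANK.__getitem__)
    return granted


def can_read(acl: ACL, actor: Optional[str]) -> bool:
    return _ACCESS_RANK[effective_access(acl, actor)] >= _ACCESS_RANK[ACCESS_READ]


def can_write(acl: ACL, actor: Optional[str]) -> bool:
    return effective_access(acl, actor) == ACCESS_READ_WRITE


def parse_acl_document(owner: str, document: dict, known_users) -> ACL:
    """Build an ACL from the JSON shape ``{safety_level, shared_with}``."""
    if not isinstance(document, dict):
        raise BadRequest("ACL document must be a JSON object")
    unknown = set(document) - {"safety_level", "shared_with"}
    if unknown:
        raise BadRequest(f"unknown ACL keys: {sorted(unknown)}")
    safety = document.get("safety_level", "private")
    shared = document.get("shared_with", {})
    if not isinstance(shared, dict):
        raise BadRequest("shared_with must map user ids to access levels")
    for user in shared:
        if user not in known_users:
            raise BadRequest(f"unknown user {user!r} in shared_with")
    if owner in shared:
        raise BadRequest("the owner cannot appear in shared_with")
    return ACL(owner=owner, safety_level=safety, shared_with=dict(shared))


class Identity:
    """Pluggable identity stub: bearer tokens mapped to user ids.

    Stands in for a real authentication backend; the HTTP layer only ever
    asks it to resolve a token and to enumerate known users.
    """

    def __init__(self):
        self._users: set[str] = set()
        self._tokens: dict[str, str] = {}

    def register(self, user: str, token: Optional[str] = None) -> str:
        """Register a user, returning their bearer token."""
        if token is None:
            token = secrets.token_hex(8)
        self._users.add(user)
        self._tokens[token] = user
        return token

    def resolve(self, token: Optional[str]) -> Optional[str]:
        if token is None:
            return None
        return self._tokens.get(token)

    @property
    def users(self) -> frozenset[str]:
        return frozenset(self._users)

    def __contains__(self, user: str) -> bool:
        return user in self._users
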