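"""Versioned persistence for data and metadata objects.

Every write produces a new immutable version of the object; versions carry
``[valid_from, valid_to)`` validity intervals that partition time from the
object's creation onward, so any historical state can be read back with an
``at_time`` timestamp.  Deletion is a tombstone version: deleted objects
vanish from live reads but their history stays reachable.

Object identifiers are 10-character base-32 (RFC 4648 alphabet) tokens.
Numeric arrays are persisted outside the version log, one HDF5 file per
array with a single dataset at the file root.
"""

from __future__ import annotations

import hashlib
import random
import tempfile
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Iterator, Optional, Sequence

import h5py
import numpy as np

from . import model
from .errors import BadRequest, Forbidden, Gone, NotFound, ValidationError
from .permissions import ACL, Identity, can_read, can_write, parse_acl_document

BASE32_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ234567"
ID_LENGTH = 10

_MICROSECOND = timedelta(microseconds=1)


def generate_id(rng: random.Random) -> str:
    """Draw a fresh 10-character RFC 4648 base-32 identifier."""
    return "".join(rng.choice(BASE32_ALPHABET) for _ in range(ID_LENGTH))


def _etag(object_id: str, valid_from: datetime) -> str:
    h = hashlib.sha1(f"{object_id}|{valid_from.isoformat()}".encode())
    return h.hexdigest()[:16]


def utcnow() -> datetime:
    return datetime.now(timezone.utc)


@dataclass(frozen=True)
class VersionedRecord:
    """One stored state of an object."""

    kind: str
    id: str
    owner: str
    fields: dict
    valid_from: datetime
    valid_to: Optional[datetime]  # None = open interval (current version)
    etag: str
    deleted: bool = False

    def covers(self, t: datetime) -> bool:
        return self.valid_from <= t and (self.valid_to is None or t < self.valid_to)


class ArrayStore:
    """HDF5-backed array persistence, one file per array.

    Each array is stored as a single dataset named ``data`` in the root of
    its own file; the file name is the array's base-32 identifier.
    """

    DATASET = "data"

    def __init__(self, root: Path, rng: random.Random):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self._rng = rng
        self._lengths: dict[str, int] = {}

    def _path(self, file_id: str) -> Path:
        return self.root / f"{file_id}.h5"

    def store_array(self, values: Sequence[float] | np.ndarray) -> model.ArrayRef:
        arr = np.asarray(values)
        if arr.ndim != 1:
            raise BadRequest("only one-dimensional arrays are supported")
        file_id = generate_id(self._rng)
        while file_id in self._lengths:
            file_id = generate_id(self._rng)
        with h5py.File(self._path(file_id), "w") as f:
            f.create_dataset(self.DATASET, data=arr)
        self._lengths[file_id] = len(arr)
        return model.ArrayRef(
            file_id=file_id, length=len(arr), dtype=str(arr.dtype), units=""
        )

    def load_array(
        self,
        file_id: str,
        first: Optional[int] = None,
        last: Optional[int] = None,
    ) -> np.ndarray:
        """Load a stored array, optionally only elements ``first..last``
        (0-based, both inclusive)."""
        if file_id not in self._lengths:
            raise NotFound(f"no such datafile {file_id!r}")
        length = self._lengths[file_id]
        with h5py.File(self._path(file_id), "r") as f:
            ds = f[self.DATASET]
            if first is None and last is None:
                return ds[()]
            first = 0 if first is None else first
            last = length - 1 if last is None else last
            if not (0 <= first <= last < length):
                raise BadRequest(
                    f"index bounds ({first}, {last}) invalid for length {length}"
                )
            return ds[first : last + 1]

    def __contains__(self, file_id: str) -> bool:
        return file_id in self._lengths

    def length(self, file_id: str) -> int:
        if file_id not in self._lengths:
            raise NotFound(f"no such datafile {file_id!r}")
        return self._lengths[file_id]


class ObjectStore:
    """In-memory version log plus on-disk HDF5 array files.

    The store enforces schema validation, per-object ACLs and monotonically
    increasing version timestamps.  All operations take an ``actor`` (user
    id or None for anonymous) and an optional explicit ``now`` timestamp;
    without one, a monotonic UTC clock is used.
    """

    def __init__(
        self,
        root: Optional[Path | str] = None,
        rng: Optional[random.Random] = None,
        identity: Optional[Identity] = None,
    ):
        if root is None:
            self._tmpdir = tempfile.TemporaryDirectory(prefix="ephyshub-")
            root = self._tmpdir.name
        self.root = Path(root)
        self.rng = rng or random.Random()
        self.identity = identity or Identity()
        self.arrays = ArrayStore(self.root / "arrays", self.rng)
        self._versions: dict[str, list[VersionedRecord]] = {}
        self._acls: dict[str, ACL] = {}
        self._last_tick = datetime.min.replace(tzinfo=timezone.utc)

    # -- clock ------------------------------------------------------------

    def _tick(self, now: Optional[datetime]) -> datetime:
        if now is None:
            now = utcnow()
            if now <= self._last_tick:
                now = self._last_tick + _MICROSECOND
        elif now.tzinfo is None:
            now = now.replace(tzinfo=timezone.utc)
        self._last_tick = max(self._last_tick, now)
        return now

    # -- identifiers ------------------------------------------------------

    def new_id(self) -> str:
        token = generate_id(self.rng)
        while token in self._versions or token in self.arrays:
            token = generate_id(self.rng)
        return token

    # -- internal helpers -------------------------------------------------

    def _live(self, object_id: str) -> Optional[VersionedRecord]:
        versions = self._versions.get(object_id)
        if not versions:
            return None
        head = versions[-1]
        return None if head.deleted else head

    def _resolver(self, object_id: str) -> Optional[tuple[str, dict]]:
        rec = self._live(object_id)
        return None if rec is None else (rec.kind, rec.fields)

    def _persist_arrays(self, kind: str, fields: dict) -> dict:
        schema = model.schema_for(kind)
        out = dict(fields)
        for attr in schema.attributes:
            val = out.get(attr.name)
            if isinstance(val, model.ArrayValue):
                ref = self.arrays.store_array(val.values)
                out[attr.name] = replace(ref, units=val.units)
        return out

    def _validate(self, kind: str, fields: dict, object_id: Optional[str]) -> None:
        violations = model.validate_object(
            kind, fields, object_id=object_id, resolver=self._resolver
        )
        if violations:
            raise ValidationError(violations)

    def acl_of(self, object_id: str) -> ACL:
        return self._acls[object_id]

    # -- CRUD -------------------------------------------------------------

    def create_object(
        self,
        kind: str,
        fields: dict,
        owner: str,
        now: Optional[datetime] = None,
    ) -> VersionedRecord:
        self._validate(kind, fields, None)
        now = self._tick(now)
        object_id = self.new_id()
        stored = self._persist_arrays(kind, fields)
        record = VersionedRecord(
            kind=kind,
            id=object_id,
            owner=owner,
            fields=stored,
            valid_from=now,
            valid_to=None,
            etag=_etag(object_id, now),
        )
        self._versions[object_id] = [record]
        self._acls[object_id] = ACL(owner=owner)
        return record

    def _append_version(
        self, object_id: str, fields: dict, now: datetime, deleted: bool = False
    ) -> VersionedRecord:
        versions = self._versions[object_id]
        head = versions[-1]
        if now <= head.valid_from:
            raise BadRequest("timestamp must be after the latest version")
        versions[-1] = replace(head, valid_to=now)
        record = VersionedRecord(
            kind=head.kind,
            id=object_id,
            owner=head.owner,
            fields=fields,
            valid_from=now,
            valid_to=None,
            etag=_etag(object_id, now),
            deleted=deleted,
        )
        versions.append(record)
        return record

    def update_object(
        self,
        object_id: str,
        partial_fields: dict,
        actor: Optional[str],
        now: Optional[datetime] = None,
    ) -> VersionedRecord:
        versions = self._versions.get(object_id)
        if versions is None:
            raise NotFound(f"no such object {object_id!r}")
        if versions[-1].deleted:
            raise Gone(f"object {object_id!r} has been deleted")
        if not can_write(self._acls[object_id], actor):
            raise Forbidden(f"no write access to {object_id!r}")
        head = versions[-1]
        stored = self._persist_arrays(head.kind, partial_fields)
        merged = {**head.fields, **stored}
        merged = {k: v for k, v in merged.items() if v is not None}
        self._validate(head.kind, merged, object_id)
        return self._append_version(object_id, merged, self._tick(now))

    def delete_object(
        self,
        object_id: str,
        actor: Optional[str],
        now: Optional[datetime] = None,
    ) -> None:
        versions = self._versions.get(object_id)
        if versions is None or versions[-1].deleted:
            raise NotFound(f"no such object {object_id!r}")
        if not can_write(self._acls[object_id], actor):
            raise Forbidden(f"no write access to {object_id!r}")
        self._append_version(
            object_id, dict(versions[-1].fields), self._tick(now), deleted=True
        )

    def get_object(
        self,
        object_id: str,
        actor: Optional[str],
        at_time: Optional[datetime] = None,
    ) -> VersionedRecord:
        versions = self._versions.get(object_id)
        if versions is None:
            raise NotFound(f"no such object {object_id!r}")
        if not can_read(self._acls[object_id], actor):
            raise Forbidden(f"no read access to {object_id!r}")
        if at_time is None:
            head = versions[-1]
            if head.deleted:
                raise NotFound(f"no such object {object_id!r}")
            return head
        if at_time.tzinfo is None:
            at_time = at_time.replace(tzinfo=timezone.utc)
        for record in versions:
            if record.covers(at_time):
                if record.deleted:
                    raise NotFound(
                        f"object {object_id!r} was deleted at the requested time"
                    )
                return record
        raise NotFound(f"object {object_id!r} did not exist at the requested time")

    # -- annotation --------------------------------------------------------

    def annotate(
        self,
        target_id: str,
        value_ids: Sequence[str],
        actor: Optional[str],
        now: Optional[datetime] = None,
    ) -> VersionedRecord:
        """Link metadata values to a data object (set semantics).

        Adding only already-present links is a no-op and does not create a
        new version.
        """
        versions = self._versions.get(target_id)
        if versions is None or versions[-1].deleted:
            raise NotFound(f"no such object {target_id!r}")
        if not can_write(self._acls[target_id], actor):
            raise Forbidden(f"no write access to {target_id!r}")
        for vid in value_ids:
            rec = self._live(vid)
            if rec is None:
                raise NotFound(f"no such metadata value {vid!r}")
            if rec.kind != "value":
                raise BadRequest(f"object {vid!r} is a {rec.kind}, not a value")
        head = versions[-1]
        existing = set(head.fields.get("metadata", ()))
        combined = sorted(existing | set(value_ids))
        if combined == sorted(existing):
            return head
        fields = {**head.fields, "metadata": combined}
        return self._append_version(target_id, fields, self._tick(now))

    # -- ACL ---------------------------------------------------------------

    def get_acl(self, object_id: str, actor: Optional[str]) -> ACL:
        if object_id not in self._versions:
            raise NotFound(f"no such object {object_id!r}")
        acl = self._acls[object_id]
        if actor != acl.owner:
            raise Forbidden("only the owner may inspect permissions")
        return acl

    def set_acl(
        self,
        object_id: str,
        document: dict,
        actor: Optional[str],
        recursive: bool = False,
    ) -> ACL:
        if object_id not in self._versions:
            raise NotFound(f"no such object {object_id!r}")
        acl = self._acls[object_id]
        if actor != acl.owner:
            raise Forbidden("only the owner may change permissions")
        new_acl = parse_acl_document(acl.owner, document, self.identity.users)
        self._acls[object_id] = new_acl
        if recursive:
            for child_id in self._contained_ids(object_id):
                if self._acls[child_id].owner == actor:
                    self._acls[child_id] = parse_acl_document(
                        actor, document, self.identity.users
                    )
        return new_acl

    def _contained_ids(self, root_id: str) -> list[str]:
        """Transitive closure of objects whose parent links reach root_id."""
        out: list[str] = []
        frontier = {root_id}
        while frontier:
            found = set()
            for oid, versions in self._versions.items():
                head = versions[-1]
                if head.deleted or oid in frontier or oid in out:
                    continue
                schema = model.schema_for(head.kind)
                for parent in schema.parents:
                    if head.fields.get(parent.name) in frontier:
                        found.add(oid)
                        break
            out.extend(sorted(found))
            frontier = found
        return out

    # -- iteration (query engine support) ----------------------------------

    def ids_of_kind(self, kind: str) -> list[str]:
        return [
            oid
            for oid, versions in self._versions.items()
            if versions[-1].kind == kind
        ]

    def version_at(
        self, object_id: str, at_time: Optional[datetime]
    ) -> Optional[VersionedRecord]:
        """Version visible at ``at_time`` (live head when None); None if
        absent or deleted then."""
        versions = self._versions.get(object_id)
        if versions is None:
            return None
        if at_time is None:
            head = versions[-1]
            return None if head.deleted else head
        for record in versions:
            if record.covers(at_time):
                return None if record.deleted else record
        return None

    def all_versions(self, object_id: str) -> list[VersionedRecord]:
        return list(self._versions.get(object_id, ()))

    def __contains__(self, object_id: str) -> bool:
        return object_id in self._versions

    # -- array passthrough --------------------------------------------------

    def store_array(self, values) -> model.ArrayRef:
        return self.arrays.store_array(values)

    def load_array(self, file_id, first=None, last=None) -> np.ndarray:
        return self.arrays.load_array(file_id, first, last)
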