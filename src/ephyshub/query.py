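"""Attribute and relationship filtering over the object store.

The query dialect follows the Django field-lookup convention: a parameter
``name__icontains=luminance`` filters on the ``name`` attribute, and
``property__name__icontains=luminance`` reaches through the ``property``
parent link of a value object.  Multiple filters combine with AND.  Reserved
parameters (``owner``, ``at_time``, ``offset``, ``max_results``,
``metadata``) select ownership, historical version, pagination window and
required annotation links; time-slicing keys are left to the HTTP layer.

Results are restricted to what the requesting user may read, ordered by
(creation time of the current version, id), and paginated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

from . import model
from .errors import BadRequest
from .permissions import can_read
from .store import ObjectStore, VersionedRecord

LOOKUPS = frozenset(
    [
        "exact",
        "iexact",
        "contains",
        "icontains",
        "gt",
        "gte",
        "lt",
        "lte",
        "in",
        "startswith",
        "isnull",
    ]
)

RESERVED_KEYS = frozenset(["owner", "at_time", "offset", "max_results", "metadata"])
#: keys consumed by the partial-data-request machinery, not by queries
SLICING_KEYS = frozenset(["start_time", "end_time", "duration"])

DEFAULT_MAX_RESULTS = 100
MAX_RESULTS_CAP = 1000


@dataclass(frozen=True)
class Filter:
    relation: Optional[str]  # parent-link name, or None for a direct field
    fieldname: str
    lookup: str
    value: str


@dataclass
class QuerySpec:
    """Parsed filter set plus pagination and version selection."""

    kind: str
    filters: list[Filter] = field(default_factory=list)
    metadata_values: list[str] = field(default_factory=list)
    owner: Optional[str] = None
    at_time: Optional[datetime] = None
    offset: int = 0
    max_results: int = DEFAULT_MAX_RESULTS


def _parse_int(raw: str, key: str, minimum: int) -> int:
    try:
        value = int(raw)
    except (TypeError, ValueError):
        raise BadRequest(f"{key} must be an integer")
    if value < minimum:
        raise BadRequest(f"{key} must be >= {minimum}")
    return value


def parse_at_time(raw: str) -> datetime:
    try:
        return datetime.fromisoformat(raw)
    except ValueError:
        raise BadRequest(f"at_time is not an ISO-8601 timestamp: {raw!r}")


def parse_query_params(params: dict, kind: str) -> QuerySpec:
    """Turn URL query parameters into a :class:`QuerySpec` for ``kind``.

    Raises :class:`BadRequest` for unknown lookups, unknown fields, or
    relationship paths that the kind's schema does not declare.
    """
    schema = model.schema_for(kind)
    spec = QuerySpec(kind=kind)
    for key, raw in params.items():
        if key in SLICING_KEYS:
            continue
        if key == "owner":
            spec.owner = raw
        elif key == "at_time":
            spec.at_time = parse_at_time(raw)
        elif key == "offset":
            spec.offset = _parse_int(raw, "offset", 0)
        elif key == "max_results":
            spec.max_results = min(
                _parse_int(raw, "max_results", 1), MAX_RESULTS_CAP
            )
        elif key == "metadata":
            spec.metadata_values = [v for v in raw.split(",") if v]
        else:
            spec.filters.append(_parse_filter_key(schema, key, raw))
    return spec


def _parse_filter_key(schema: model.KindSchema, key: str, raw: str) -> Filter:
    parts = key.split("__")
    if parts[-1] in LOOKUPS:
        lookup = parts[-1]
        parts = parts[:-1]
    else:
        lookup = "exact"
    if len(parts) == 1:
        relation, fieldname = None, parts[0]
        target = schema
    elif len(parts) == 2:
        relation, fieldname = parts
        parent = schema.parent(relation)
        if parent is None:
            raise BadRequest(
                f"kind {schema.kind!r} has no relationship {relation!r}"
            )
        target = model.schema_for(parent.target_kinds[0])
    else:
        raise BadRequest(f"filter path too deep: {key!r}")
    if "__" in fieldname or not fieldname:
        raise BadRequest(f"malformed filter key {key!r}")
    if target.attr(fieldname) is None and target.parent(fieldname) is None:
        raise BadRequest(
            f"kind {target.kind!r} has no attribute {fieldname!r}"
        )
    return Filter(relation=relation, fieldname=fieldname, lookup=lookup, value=raw)


# --------------------------------------------------------------------------
# Evaluation

def _comparable(stored, raw: str):
    """Coerce the URL string to the stored value's type for comparison."""
    if isinstance(stored, model.Quantity):
        # quantities compare on their canonical base-unit magnitude
        stored = stored.to(model.BASE_UNIT[stored.dimension]).value
    if isinstance(stored, bool):
        return stored, raw.lower() in ("true", "1")
    if isinstance(stored, (int, float)):
        try:
            return stored, float(raw)
        except ValueError:
            return stored, None
    return stored, raw


def match_filter(stored, lookup: str, raw: str) -> bool:
    """Apply one field lookup to a stored attribute value."""
    if lookup == "isnull":
        want_null = raw.lower() in ("true", "1")
        return (stored is None) == want_null
    if stored is None:
        return False
    if isinstance(stored, model.Quantity):
        stored = stored.to(model.BASE_UNIT[stored.dimension]).value
    if lookup == "exact":
        s, v = _comparable(stored, raw)
        return v is not None and s == v
    if lookup == "iexact":
        return str(stored).lower() == raw.lower()
    if lookup == "contains":
        return raw in str(stored)
    if lookup == "icontains":
        return raw.lower() in str(stored).lower()
    if lookup == "startswith":
        return str(stored).startswith(raw)
    if lookup == "in":
        return any(match_filter(stored, "exact", part) for part in raw.split(","))
    if lookup in ("gt", "gte", "lt", "lte"):
        s, v = _comparable(stored, raw)
        if isinstance(s, str):
            v = raw
        elif v is None:
            return False
        return {
            "gt": s > v,
            "gte": s >= v,
            "lt": s < v,
            "lte": s <= v,
        }[lookup]
    raise BadRequest(f"unknown lookup {lookup!r}")


def _record_matches(
    store: ObjectStore,
    record: VersionedRecord,
    flt: Filter,
    at_time: Optional[datetime],
) -> bool:
    if flt.relation is None:
        return match_filter(record.fields.get(flt.fieldname), flt.lookup, flt.value)
    parent_id = record.fields.get(flt.relation)
    if parent_id is None:
        return flt.lookup == "isnull" and flt.value.lower() in ("true", "1")
    parent = store.version_at(parent_id, at_time)
    if parent is None:
        return False
    return match_filter(parent.fields.get(flt.fieldname), flt.lookup, flt.value)


def evaluate_query(
    spec: QuerySpec, actor: Optional[str], store: ObjectStore
) -> tuple[list[VersionedRecord], int]:
    """Run a query; returns (page of records, total matching count).

    Visibility equals per-object read access; with ``at_time`` the version
    selection happens before any filtering.
    """
    matches: list[VersionedRecord] = []
    for oid in store.ids_of_kind(spec.kind):
        record = store.version_at(oid, spec.at_time)
        if record is None:
            continue
        if not can_read(store.acl_of(oid), actor):
            continue
        if spec.owner is not None and record.owner != spec.owner:
            continue
        if spec.metadata_values:
            linked = set(record.fields.get("metadata", ()))
            if not set(spec.metadata_values) <= linked:
                continue
        if all(
            _record_matches(store, record, flt, spec.at_time)
            for flt in spec.filters
        ):
            matches.append(record)
    matches.sort(key=lambda r: (r.valid_from, r.id))
    total = len(matches)
    page = matches[spec.offset : spec.offset + spec.max_results]
    return page, total
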