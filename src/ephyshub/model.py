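"""Unified data + metadata object model.

The model combines two established representations from electrophysiology:
a Neo-style hierarchy for recorded data (a *block* holds experimental
trials — *segments* — which hold regularly sampled *analogsignals*,
*spiketrains* of sorted *units*, and stimulus *events*; *recordingchannels*
grouped in a *recordingchannelgroup* mark the electrodes) and an odML-style
hierarchy for metadata (nested *sections* holding *properties* whose
*values* carry the actual numbers or strings).  Any data object can be
annotated by linking it to metadata values, which makes data selectable by
experimental context.

Physical quantities are plain ``(value, units)`` pairs over a closed unit
table (time: s/ms/us, frequency: Hz/kHz, voltage: V/mV/uV).  Unknown unit
symbols are errors, never passed through.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .errors import UnitDimensionError, UnknownKindError

# --------------------------------------------------------------------------
# Units

#: dimension -> unit symbol -> factor to the base unit of that dimension
UNIT_TABLE: dict[str, dict[str, float]] = {
    "time": {"s": 1.0, "ms": 1e-3, "us": 1e-6},
    "frequency": {"Hz": 1.0, "kHz": 1e3},
    "voltage": {"V": 1.0, "mV": 1e-3, "uV": 1e-6},
}

BASE_UNIT = {"time": "s", "frequency": "Hz", "voltage": "V"}

DIMENSION_OF = {
    symbol: dim for dim, units in UNIT_TABLE.items() for symbol in units
}


@dataclass(frozen=True)
class Quantity:
    """A numeric value with a unit symbol from the supported table."""

    value: float
    units: str

    @property
    def dimension(self) -> str:
        try:
            return DIMENSION_OF[self.units]
        except KeyError:
            raise UnitDimensionError(f"unknown unit symbol {self.units!r}")

    def to(self, units: str) -> "Quantity":
        """Convert to another unit of the same dimension (exact rescale)."""
        target_dim = DIMENSION_OF.get(units)
        if target_dim is None:
            raise UnitDimensionError(f"unknown unit symbol {units!r}")
        if target_dim != self.dimension:
            raise UnitDimensionError(
                f"cannot convert {self.units!r} ({self.dimension}) "
                f"to {units!r} ({target_dim})"
            )
        factor = UNIT_TABLE[target_dim][self.units] / UNIT_TABLE[target_dim][units]
        return Quantity(self.value * factor, units)


def canonicalize_quantity(q: Quantity, expected_dimension: str) -> Quantity:
    """Rescale ``q`` to the base unit (s, Hz, V) of ``expected_dimension``.

    Raises :class:`UnitDimensionError` if the symbol is unknown or belongs
    to a different dimension.
    """
    if expected_dimension not in UNIT_TABLE:
        raise UnitDimensionError(f"unknown dimension {expected_dimension!r}")
    if q.dimension != expected_dimension:
        raise UnitDimensionError(
            f"expected a {expected_dimension} quantity, got units {q.units!r}"
        )
    return q.to(BASE_UNIT[expected_dimension])


# --------------------------------------------------------------------------
# Array values

@dataclass(frozen=True)
class ArrayValue:
    """An in-memory numeric array with units, not yet persisted."""

    values: np.ndarray
    units: str

    def __eq__(self, other):
        return (
            isinstance(other, ArrayValue)
            and self.units == other.units
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class ArrayRef:
    """Reference to a persisted array (one HDF5 dataset at file root)."""

    file_id: str
    length: int
    dtype: str
    units: str


# --------------------------------------------------------------------------
# Kind schemas

DATA_KINDS = (
    "block",
    "segment",
    "analogsignal",
    "spiketrain",
    "event",
    "recordingchannelgroup",
    "recordingchannel",
    "unit",
)
METADATA_KINDS = ("section", "property", "value")
ALL_KINDS = DATA_KINDS + METADATA_KINDS


@dataclass(frozen=True)
class AttrSpec:
    name: str
    type: str  # text | scalar | int | quantity | array
    required: bool = False
    dimension: Optional[str] = None  # for quantity/array fields


@dataclass(frozen=True)
class ParentSpec:
    name: str
    target_kinds: tuple[str, ...]
    required: bool = False


@dataclass(frozen=True)
class KindSchema:
    kind: str
    namespace: str
    attributes: tuple[AttrSpec, ...] = ()
    parents: tuple[ParentSpec, ...] = ()

    def attr(self, name: str) -> Optional[AttrSpec]:
        for a in self.attributes:
            if a.name == name:
                return a
        return None

    def parent(self, name: str) -> Optional[ParentSpec]:
        for p in self.parents:
            if p.name == name:
                return p
        return None

    @property
    def field_names(self) -> set[str]:
        return {a.name for a in self.attributes} | {p.name for p in self.parents}


_COMMENT = AttrSpec("comment", "text")

SCHEMAS: dict[str, KindSchema] = {
    s.kind: s
    for s in [
        KindSchema(
            "block",
            "electrophysiology",
            (AttrSpec("name", "text", required=True), _COMMENT),
        ),
        KindSchema(
            "segment",
            "electrophysiology",
            (AttrSpec("name", "text", required=True), _COMMENT),
            (ParentSpec("block", ("block",)),),
        ),
        KindSchema(
            "analogsignal",
            "electrophysiology",
            (
                AttrSpec("name", "text", required=True),
                AttrSpec("t_start", "quantity", required=True, dimension="time"),
                AttrSpec(
                    "sampling_rate", "quantity", required=True, dimension="frequency"
                ),
                AttrSpec("signal", "array", required=True, dimension="voltage"),
                _COMMENT,
            ),
            (
                ParentSpec("segment", ("segment",), required=True),
                ParentSpec("recordingchannel", ("recordingchannel",)),
            ),
        ),
        KindSchema(
            "spiketrain",
            "electrophysiology",
            (
                AttrSpec("name", "text", required=True),
                AttrSpec("t_start", "quantity", required=True, dimension="time"),
                AttrSpec("t_stop", "quantity", required=True, dimension="time"),
                AttrSpec("times", "array", required=True, dimension="time"),
                _COMMENT,
            ),
            (
                ParentSpec("segment", ("segment",), required=True),
                ParentSpec("unit", ("unit",)),
            ),
        ),
        KindSchema(
            "event",
            "electrophysiology",
            (
                AttrSpec("label", "text", required=True),
                AttrSpec("time", "quantity", required=True, dimension="time"),
                _COMMENT,
            ),
            (ParentSpec("segment", ("segment",), required=True),),
        ),
        KindSchema(
            "recordingchannelgroup",
            "electrophysiology",
            (AttrSpec("name", "text", required=True), _COMMENT),
            (ParentSpec("block", ("block",)),),
        ),
        KindSchema(
            "recordingchannel",
            "electrophysiology",
            (
                AttrSpec("name", "text", required=True),
                AttrSpec("index", "int"),
                _COMMENT,
            ),
            (ParentSpec("recordingchannelgroup", ("recordingchannelgroup",)),),
        ),
        KindSchema(
            "unit",
            "electrophysiology",
            (AttrSpec("name", "text", required=True), _COMMENT),
            (ParentSpec("recordingchannelgroup", ("recordingchannelgroup",)),),
        ),
        KindSchema(
            "section",
            "metadata",
            (AttrSpec("name", "text", required=True), _COMMENT),
            (
                ParentSpec("parent_section", ("section",)),
                ParentSpec("block", ("block",)),
            ),
        ),
        KindSchema(
            "property",
            "metadata",
            (AttrSpec("name", "text", required=True), _COMMENT),
            (ParentSpec("section", ("section",), required=True),),
        ),
        KindSchema(
            "value",
            "metadata",
            (AttrSpec("data", "scalar", required=True), _COMMENT),
            (ParentSpec("property", ("property",), required=True),),
        ),
    ]
}

NAMESPACE_OF_KIND = {k: s.namespace for k, s in SCHEMAS.items()}

KINDS_BY_NAMESPACE: dict[str, tuple[str, ...]] = {
    "electrophysiology": DATA_KINDS,
    "metadata": METADATA_KINDS,
}


def schema_for(kind: str) -> KindSchema:
    try:
        return SCHEMAS[kind]
    except KeyError:
        raise UnknownKindError(f"unknown object kind {kind!r}")


# --------------------------------------------------------------------------
# Validation

# resolver(object_id) -> (kind, fields) or None; supplied by the store so
# that parent kinds and section-cycle checks can see the surrounding graph.
Resolver = Callable[[str], Optional[tuple[str, dict]]]


def _check_quantity(spec: AttrSpec, val, violations: list[str]) -> None:
    if not isinstance(val, Quantity):
        violations.append(f"attribute {spec.name!r} must be a quantity")
        return
    try:
        canonicalize_quantity(val, spec.dimension)
    except UnitDimensionError:
        violations.append(
            f"attribute {spec.name!r} has wrong unit dimension "
            f"(expected {spec.dimension}, got {val.units!r})"
        )


def _check_array(spec: AttrSpec, val, violations: list[str]) -> None:
    if not isinstance(val, (ArrayValue, ArrayRef)):
        violations.append(f"attribute {spec.name!r} must be an array")
        return
    if DIMENSION_OF.get(val.units) != spec.dimension:
        violations.append(
            f"array {spec.name!r} has wrong unit dimension "
            f"(expected {spec.dimension}, got {val.units!r})"
        )


def validate_object(
    kind: str,
    fields: dict,
    *,
    object_id: Optional[str] = None,
    resolver: Optional[Resolver] = None,
) -> list[str]:
    """Check ``fields`` against the declarative schema for ``kind``.

    Returns a list of human-readable violations; an empty list means the
    object is valid.  With a ``resolver`` the check extends to parent kinds
    and to section-nesting cycles; without one, only local structure is
    checked.  Unknown kinds raise :class:`UnknownKindError`.
    """
    schema = schema_for(kind)
    violations: list[str] = []

    for name in fields:
        if name == "metadata":  # annotation links, managed by the store
            continue
        if name not in schema.field_names:
            violations.append(f"unknown attribute {name!r} for kind {kind!r}")

    for attr in schema.attributes:
        val = fields.get(attr.name)
        if val is None:
            if attr.required:
                violations.append(f"missing required attribute {attr.name!r}")
            continue
        if attr.type == "quantity":
            _check_quantity(attr, val, violations)
        elif attr.type == "array":
            _check_array(attr, val, violations)
        elif attr.type == "text":
            if not isinstance(val, str):
                violations.append(f"attribute {attr.name!r} must be text")
        elif attr.type == "int":
            if not isinstance(val, int) or isinstance(val, bool):
                violations.append(f"attribute {attr.name!r} must be an integer")
        elif attr.type == "scalar":
            if not isinstance(val, (str, int, float)) or isinstance(val, bool):
                violations.append(
                    f"attribute {attr.name!r} must be text or a number"
                )

    for parent in schema.parents:
        pid = fields.get(parent.name)
        if pid is None:
            if parent.required:
                violations.append(f"missing required parent {parent.name!r}")
            continue
        if not isinstance(pid, str):
            violations.append(f"parent {parent.name!r} must be an object id")
            continue
        if resolver is not None:
            resolved = resolver(pid)
            if resolved is None:
                violations.append(f"parent {parent.name!r}={pid} does not exist")
            elif resolved[0] not in parent.target_kinds:
                violations.append(
                    f"parent {parent.name!r} must be one of "
                    f"{parent.target_kinds}, got {resolved[0]!r}"
                )

    if not violations and kind in ("analogsignal", "spiketrain"):
        violations.extend(_validate_signal_specifics(kind, fields))
    if not violations and kind == "section" and resolver is not None:
        violations.extend(_validate_section_chain(fields, object_id, resolver))

    return violations


def _validate_signal_specifics(kind: str, fields: dict) -> list[str]:
    violations = []
    if kind == "analogsignal":
        if fields["sampling_rate"].value <= 0:
            violations.append("sampling_rate must be positive")
    else:  # spiketrain
        t_start = canonicalize_quantity(fields["t_start"], "time").value
        t_stop = canonicalize_quantity(fields["t_stop"], "time").value
        if t_stop < t_start:
            violations.append("t_stop must not precede t_start")
        times = fields["times"]
        if isinstance(times, ArrayValue) and len(times.values):
            sec = times.values * UNIT_TABLE["time"][times.units]
            if np.any(np.diff(sec) < 0):
                # explicit over implicit: unsorted input is rejected, not sorted
                violations.append("spike times must be non-decreasing")
            elif sec[0] < t_start or sec[-1] >= t_stop:
                violations.append(
                    "spike times must lie within [t_start, t_stop)"
                )
    return violations


def _validate_section_chain(
    fields: dict, object_id: Optional[str], resolver: Resolver
) -> list[str]:
    """Sections nest freely but their parent links must form a forest."""
    seen = {object_id} if object_id else set()
    pid = fields.get("parent_section")
    while pid is not None:
        if pid in seen:
            return ["section cycle"]
        seen.add(pid)
        resolved = resolver(pid)
        if resolved is None:
            break
        pid = resolved[1].get("parent_section")
    return []
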