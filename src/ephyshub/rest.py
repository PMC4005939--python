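"""HTTP-facing layer: URL grammar, verb dispatch, JSON bodies, caching.

The resource grammar is ``/namespace/object_type/[id/[acl/]]`` with three
namespaces: ``electrophysiology`` (Neo-style data kinds), ``metadata``
(section/property/value) and ``datafiles`` (HDF5 array downloads).  The
verb table:

    ==============================  ================  ==================  ============
    URL                             GET               POST                DELETE
    ==============================  ================  ==================  ============
    /namespace/object_type/         list + filters    create/bulk update  bulk delete
    /namespace/object_type/id/      single object     update              delete
    /namespace/object_type/id/acl/  permissions       update permissions  405
    ==============================  ================  ==================  ============

All bodies are JSON except datafile downloads, which are HDF5 payloads with
one dataset at the file root.  Errors carry a JSON ``{"message": ...}``
body.  Conditional GET is supported through e-Tags (``If-None-Match``) and
``Last-Modified`` / ``If-Modified-Since``.

``route_request`` is a pure dispatcher; the WSGI adapter in
:mod:`ephyshub.wsgi` maps real HTTP traffic onto it.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from datetime import timezone
from email.utils import format_datetime, parsedate_to_datetime
from typing import Optional

import h5py
import numpy as np

from . import model, query, slicing
from .errors import (
    ApiError,
    BadRequest,
    Gone,
    MethodNotAllowed,
    NotFound,
    PreconditionFailed,
)
from .permissions import Identity
from .store import ObjectStore, VersionedRecord

logger = logging.getLogger("ephyshub.rest")

ID_RE = re.compile(r"^[A-Z2-7]{10}$")

NAMESPACES = ("electrophysiology", "metadata", "datafiles")


@dataclass
class ApiResponse:
    status: int
    headers: dict = field(default_factory=dict)
    body: object = None  # JSON-serializable document, bytes, or None


def _http_date(dt) -> str:
    return format_datetime(dt.astimezone(timezone.utc), usegmt=True)


# --------------------------------------------------------------------------
# (De)serialization

def location_of(record: VersionedRecord) -> str:
    ns = model.NAMESPACE_OF_KIND[record.kind]
    return f"/{ns}/{record.kind}/{record.id}/"


def serialize(record: VersionedRecord, bounds: Optional[dict] = None) -> dict:
    """Serialize a record to its JSON document.

    ``bounds`` optionally maps array field names to
    :class:`~ephyshub.slicing.IndexBounds` (or None for an empty slice),
    produced by a partial data request; they parameterize the datafile URL.
    """
    fields_doc: dict = {}
    for name, val in record.fields.items():
        if isinstance(val, model.Quantity):
            fields_doc[name] = {"value": val.value, "units": val.units}
        elif isinstance(val, model.ArrayRef):
            doc = {
                "url": f"/datafiles/{val.file_id}/",
                "units": val.units,
                "length": val.length,
                "dtype": val.dtype,
            }
            if bounds is not None and name in bounds:
                b = bounds[name]
                if b is None:
                    doc["url"] = None
                    doc["length"] = 0
                else:
                    doc["url"] += (
                        f"?start_index={b.first_index}&end_index={b.last_index}"
                    )
                    doc["length"] = b.count
            fields_doc[name] = doc
        else:
            fields_doc[name] = val
    return {
        "id": record.id,
        "kind": record.kind,
        "location": location_of(record),
        "owner": record.owner,
        "valid_from": record.valid_from.isoformat(),
        "valid_to": record.valid_to.isoformat() if record.valid_to else None,
        "etag": record.etag,
        "deleted": record.deleted,
        "fields": fields_doc,
    }


def deserialize(kind: str, document: dict) -> dict:
    """Convert a JSON fields document into an attribute map.

    Accepts quantity fields as ``{"value", "units"}``, array fields as
    either ``{"data": [...], "units"}`` (inline payload) or
    ``{"url"/"file_id", "units", ...}`` (reference to a stored datafile).
    Malformed entries raise :class:`BadRequest` naming the offending keys.
    """
    schema = model.schema_for(kind)
    if not isinstance(document, dict):
        raise BadRequest("request body must be a JSON object")
    fields: dict = {}
    bad: list[str] = []
    for name, raw in document.items():
        if name == "metadata":
            if not isinstance(raw, list):
                bad.append(name)
            else:
                fields[name] = [str(v) for v in raw]
            continue
        attr = schema.attr(name)
        if attr is not None and attr.type == "quantity":
            if (
                isinstance(raw, dict)
                and set(raw) >= {"value", "units"}
                and isinstance(raw["value"], (int, float))
            ):
                fields[name] = model.Quantity(float(raw["value"]), raw["units"])
            else:
                bad.append(name)
        elif attr is not None and attr.type == "array":
            if isinstance(raw, dict) and "data" in raw:
                try:
                    values = np.asarray(raw["data"], dtype=float)
                except (TypeError, ValueError):
                    bad.append(name)
                    continue
                fields[name] = model.ArrayValue(values, raw.get("units", ""))
            elif isinstance(raw, dict) and ("url" in raw or "file_id" in raw):
                fid = raw.get("file_id")
                if fid is None:
                    m = re.search(r"/datafiles/([A-Z2-7]{10})/", raw["url"] or "")
                    fid = m.group(1) if m else None
                if fid is None:
                    bad.append(name)
                    continue
                fields[name] = model.ArrayRef(
                    file_id=fid,
                    length=int(raw.get("length", 0)),
                    dtype=str(raw.get("dtype", "float64")),
                    units=raw.get("units", ""),
                )
            else:
                bad.append(name)
        else:
            # text/scalar attributes and parent ids pass through; unknown
            # names are caught by schema validation downstream
            fields[name] = raw
    if bad:
        raise BadRequest(f"malformed field entries: {sorted(bad)}", fields=sorted(bad))
    return fields


def fields_to_document(fields: dict) -> dict:
    """Inverse of :func:`deserialize`: an attribute map as a JSON body."""
    doc: dict = {}
    for name, val in fields.items():
        if isinstance(val, model.Quantity):
            doc[name] = {"value": val.value, "units": val.units}
        elif isinstance(val, model.ArrayValue):
            doc[name] = {"data": np.asarray(val.values).tolist(), "units": val.units}
        elif isinstance(val, model.ArrayRef):
            doc[name] = {
                "file_id": val.file_id,
                "length": val.length,
                "dtype": val.dtype,
                "units": val.units,
            }
        else:
            doc[name] = val
    return doc


# --------------------------------------------------------------------------
# Conditional GET

def conditional_get(headers: dict, record: VersionedRecord) -> Optional[ApiResponse]:
    """Return a 304 response when the client's cached copy is current."""
    headers = {k.lower(): v for k, v in (headers or {}).items()}
    inm = headers.get("if-none-match")
    if inm is not None and inm.strip('"') == record.etag:
        return ApiResponse(
            304,
            {"ETag": record.etag, "Last-Modified": _http_date(record.valid_from)},
            None,
        )
    ims = headers.get("if-modified-since")
    if ims is not None:
        try:
            since = parsedate_to_datetime(ims)
        except (TypeError, ValueError):
            return None
        if record.valid_from.replace(microsecond=0) <= since:
            return ApiResponse(
                304,
                {"ETag": record.etag, "Last-Modified": _http_date(record.valid_from)},
                None,
            )
    return None


# --------------------------------------------------------------------------
# Service

class RestService:
    """Verb dispatcher over one object store.

    ``actor`` is a resolved user id (or None for anonymous); token
    resolution happens in the WSGI adapter.
    """

    def __init__(
        self,
        store: Optional[ObjectStore] = None,
        identity: Optional[Identity] = None,
    ):
        self.identity = identity or Identity()
        self.store = store or ObjectStore(identity=self.identity)

    # -- entry point ------------------------------------------------------

    def route_request(
        self,
        method: str,
        path: str,
        params: Optional[dict] = None,
        body: Optional[dict] = None,
        headers: Optional[dict] = None,
        actor: Optional[str] = None,
    ) -> ApiResponse:
        params = params or {}
        headers = headers or {}
        try:
            response = self._dispatch(method.upper(), path, params, body, headers, actor)
        except ApiError as exc:
            response = ApiResponse(exc.status, {}, exc.to_json())
        logger.info(
            "%s %s -> %d actor=%s", method.upper(), path, response.status, actor
        )
        return response

    def _dispatch(self, method, path, params, body, headers, actor) -> ApiResponse:
        parts = [p for p in path.split("/") if p]
        if not parts or parts[0] not in NAMESPACES:
            raise NotFound(f"unknown namespace in {path!r}")
        ns = parts[0]
        if ns == "datafiles":
            return self._dispatch_datafile(method, parts, params)
        if len(parts) < 2:
            raise NotFound("object type missing from URL")
        otype = parts[1]
        if otype not in model.KINDS_BY_NAMESPACE[ns]:
            raise NotFound(f"unknown object type {otype!r} in namespace {ns!r}")
        if len(parts) == 2:
            return self._dispatch_collection(method, otype, params, body, actor)
        object_id = parts[2]
        if not ID_RE.match(object_id):
            raise NotFound(f"malformed object id {object_id!r}")
        if len(parts) == 3:
            return self._dispatch_single(
                method, otype, object_id, params, body, headers, actor
            )
        if len(parts) == 4 and parts[3] == "acl":
            return self._dispatch_acl(method, object_id, body, actor)
        raise NotFound(f"unrecognized URL {path!r}")

    # -- collection URLs --------------------------------------------------

    def _dispatch_collection(self, method, kind, params, body, actor) -> ApiResponse:
        if method == "GET":
            spec = query.parse_query_params(params, kind)
            records, total = query.evaluate_query(spec, actor, self.store)
            slice_params = {k: params[k] for k in query.SLICING_KEYS if k in params}
            objects = [
                serialize(r, self._slice_bounds(r, slice_params)) for r in records
            ]
            return ApiResponse(
                200,
                {},
                {
                    "objects": objects,
                    "total": total,
                    "offset": spec.offset,
                    "max_results": spec.max_results,
                },
            )
        if method == "POST":
            if actor is None:
                raise BadRequest("authentication required to create or update")
            if isinstance(body, dict) and "fields" in body:
                return self._bulk_update(kind, body, actor)
            fields = deserialize(kind, body or {})
            record = self.store.create_object(kind, fields, owner=actor)
            return ApiResponse(
                201,
                {"ETag": record.etag, "Location": location_of(record)},
                serialize(record),
            )
        if method == "DELETE":
            spec = query.parse_query_params(params, kind)
            records, _ = query.evaluate_query(spec, actor, self.store)
            deleted = 0
            for record in records:
                try:
                    self.store.delete_object(record.id, actor)
                    deleted += 1
                except ApiError:
                    continue
            return ApiResponse(200, {}, {"deleted": deleted})
        raise MethodNotAllowed(f"{method} not supported on collection URLs")

    def _bulk_update(self, kind, body, actor) -> ApiResponse:
        fields_doc = body.get("fields")
        if not isinstance(fields_doc, dict):
            raise BadRequest("bulk update body must carry a fields object")
        ids = body.get("ids")
        if ids is None:
            spec = query.parse_query_params(body.get("filters") or {}, kind)
            records, _ = query.evaluate_query(spec, actor, self.store)
            ids = [r.id for r in records]
        partial = deserialize(kind, fields_doc)
        updated = []
        for oid in ids:
            record = self.store.update_object(oid, partial, actor)
            updated.append(record.id)
        return ApiResponse(200, {}, {"updated": updated})

    # -- single-object URLs ------------------------------------------------

    def _get_record(self, kind, object_id, actor, at_time=None) -> VersionedRecord:
        record = self.store.get_object(object_id, actor, at_time=at_time)
        if record.kind != kind:
            raise NotFound(f"no {kind} with id {object_id!r}")
        return record

    def _dispatch_single(
        self, method, kind, object_id, params, body, headers, actor
    ) -> ApiResponse:
        if method == "GET":
            at_time = (
                query.parse_at_time(params["at_time"]) if "at_time" in params else None
            )
            record = self._get_record(kind, object_id, actor, at_time)
            if at_time is None:
                cached = conditional_get(headers, record)
                if cached is not None:
                    return cached
            slice_params = {k: params[k] for k in query.SLICING_KEYS if k in params}
            bounds = self._slice_bounds(record, slice_params)
            return ApiResponse(
                200,
                {
                    "ETag": record.etag,
                    "Last-Modified": _http_date(record.valid_from),
                },
                serialize(record, bounds),
            )
        if method == "POST":
            versions = self.store.all_versions(object_id)
            if versions and versions[-1].deleted and versions[-1].kind == kind:
                raise Gone(
                    f"object {object_id!r} was deleted and cannot be updated"
                )
            current = self._get_record(kind, object_id, actor)
            if_match = {k.lower(): v for k, v in headers.items()}.get("if-match")
            if if_match is not None and if_match.strip('"') != current.etag:
                raise PreconditionFailed("stale e-Tag; object was modified")
            doc = dict(body or {})
            value_ids = doc.pop("metadata", None)
            record = current
            if doc:
                partial = deserialize(kind, doc)
                record = self.store.update_object(object_id, partial, actor)
            if value_ids is not None:
                record = self.store.annotate(object_id, value_ids, actor)
            return ApiResponse(200, {"ETag": record.etag}, serialize(record))
        if method == "DELETE":
            self._get_record(kind, object_id, actor)
            self.store.delete_object(object_id, actor)
            return ApiResponse(200, {}, {"message": f"object {object_id} deleted"})
        raise MethodNotAllowed(f"{method} not supported on object URLs")

    # -- ACL URLs -----------------------------------------------------------

    def _dispatch_acl(self, method, object_id, body, actor) -> ApiResponse:
        if method == "GET":
            acl = self.store.get_acl(object_id, actor)
            return ApiResponse(200, {}, acl.to_json())
        if method == "POST":
            doc = dict(body or {})
            recursive = bool(doc.pop("recursive", False))
            acl = self.store.set_acl(object_id, doc, actor, recursive=recursive)
            return ApiResponse(200, {}, acl.to_json())
        raise MethodNotAllowed("405 Not Supported")

    # -- datafiles ----------------------------------------------------------

    def _dispatch_datafile(self, method, parts, params) -> ApiResponse:
        if len(parts) != 2:
            raise NotFound("datafile URLs have the form /datafiles/<id>/")
        if method != "GET":
            raise MethodNotAllowed("datafiles are read-only over HTTP")
        file_id = parts[1]
        if not ID_RE.match(file_id):
            raise NotFound(f"malformed datafile id {file_id!r}")

        def _index(key):
            if key not in params:
                return None
            try:
                return int(params[key])
            except (TypeError, ValueError):
                raise BadRequest(f"{key} must be an integer")

        payload = self.serve_datafile(
            file_id, _index("start_index"), _index("end_index")
        )
        return ApiResponse(200, {"Content-Type": "application/x-hdf5"}, payload)

    def serve_datafile(
        self,
        file_id: str,
        start_index: Optional[int] = None,
        end_index: Optional[int] = None,
    ) -> bytes:
        """Build an HDF5 payload with a single root dataset for the array.

        With index bounds, only elements ``start_index..end_index``
        (inclusive) are included; the payload carries raw numbers only, no
        units or signal attributes.
        """
        values = self.store.load_array(file_id, start_index, end_index)
        buf = io.BytesIO()
        with h5py.File(buf, "w") as f:
            f.create_dataset("data", data=values)
        return buf.getvalue()

    # -- partial data requests ----------------------------------------------

    def _slice_bounds(self, record: VersionedRecord, slice_params: dict):
        """Resolve slicing query keys into per-array-field index bounds.

        Raw numeric parameter values are interpreted in the units of the
        object's ``t_start`` attribute; datafile payloads carry no units,
        so all meta information stays on the object.
        """
        if not slice_params or record.kind not in ("analogsignal", "spiketrain"):
            return None
        t_start = record.fields["t_start"]
        qparams = {}
        for key, raw in slice_params.items():
            try:
                qparams[key] = model.Quantity(float(raw), t_start.units)
            except (TypeError, ValueError):
                raise BadRequest(f"{key} must be a number")
        if record.kind == "analogsignal":
            ref = record.fields["signal"]
            rate = model.canonicalize_quantity(
                record.fields["sampling_rate"], "frequency"
            ).value
            t0 = model.canonicalize_quantity(t_start, "time").value
            t_stop = model.Quantity(t0 + ref.length / rate, "s")
            window = slicing.resolve_slice_window(qparams, t_start, t_stop)
            bounds = slicing.slice_indices(
                window, t_start, record.fields["sampling_rate"], ref.length
            )
            return {"signal": bounds}
        # spiketrain
        window = slicing.resolve_slice_window(
            qparams, t_start, record.fields["t_stop"]
        )
        ref = record.fields["times"]
        times = self.store.load_array(ref.file_id)
        factor = model.UNIT_TABLE["time"][ref.units]
        bounds = slicing.spiketrain_index_bounds(times * factor, window)
        return {"times": bounds}
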