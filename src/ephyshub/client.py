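"""Native client library: remote objects without visible HTTP plumbing.

A :class:`Session` speaks the REST contract through a pluggable transport —
either real HTTP (:class:`HttpTransport`, stdlib urllib) or an in-process
call into a :class:`~ephyshub.rest.RestService` (:class:`InProcessTransport`,
handy for tests and embedded use).  Remote objects keep their numeric
arrays as lazy references; the data is only transferred when
:meth:`Session.fetch_array` is called, optionally for a time window so the
server slices before sending.

Cached documents are revalidated with conditional GETs: the session stores
the last seen e-Tag per location and the server answers 304 when nothing
changed, in which case the cached copy is reused.
"""

from __future__ import annotations

import io
import json
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field as dc_field
from typing import Optional

import h5py
import numpy as np

from . import model, rest
from .errors import ValidationError
from .slicing import SliceWindow


class ClientError(Exception):
    """An error response surfaced from the server."""

    def __init__(self, status: int, message: str):
        super().__init__(f"HTTP {status}: {message}")
        self.status = status
        self.message = message


class ConflictError(ClientError):
    """Optimistic-concurrency failure: the object changed under us."""


class ConnectionFailed(Exception):
    """The server could not be reached at all."""


@dataclass
class RemoteObject:
    """Client-side view of one stored object."""

    kind: str
    fields: dict = dc_field(default_factory=dict)
    id: Optional[str] = None
    etag: Optional[str] = None
    location: Optional[str] = None
    owner: Optional[str] = None

    @classmethod
    def from_document(cls, doc: dict) -> "RemoteObject":
        return cls(
            kind=doc["kind"],
            fields=rest.deserialize(doc["kind"], doc["fields"]),
            id=doc["id"],
            etag=doc["etag"],
            location=doc["location"],
            owner=doc.get("owner"),
        )


class InProcessTransport:
    """Direct dispatch into a RestService, bypassing sockets."""

    def __init__(self, service: rest.RestService, token: Optional[str] = None):
        self.service = service
        self.token = token

    def request(self, method, path, params=None, body=None, headers=None):
        actor = self.service.identity.resolve(self.token)
        response = self.service.route_request(
            method, path, params=params, body=body, headers=headers, actor=actor
        )
        return response.status, dict(response.headers), response.body


class HttpTransport:
    """Transport over real HTTP using the standard library."""

    def __init__(self, base_url: str, token: Optional[str] = None, timeout: float = 30.0):
        self.base_url = base_url.rstrip("/")
        self.token = token
        self.timeout = timeout

    def request(self, method, path, params=None, body=None, headers=None):
        url = self.base_url + path
        if params:
            url += "?" + urllib.parse.urlencode(params)
        data = json.dumps(body).encode() if body is not None else None
        req = urllib.request.Request(url, data=data, method=method)
        req.add_header("Content-Type", "application/json")
        if self.token:
            req.add_header("Authorization", f"Bearer {self.token}")
        for key, value in (headers or {}).items():
            req.add_header(key, value)
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                return resp.status, dict(resp.headers), self._decode(resp)
        except urllib.error.HTTPError as exc:
            raw = exc.read()
            try:
                parsed = json.loads(raw)
            except ValueError:
                parsed = {"message": raw.decode(errors="replace")}
            return exc.code, dict(exc.headers), parsed
        except urllib.error.URLError as exc:
            raise ConnectionFailed(str(exc.reason))

    @staticmethod
    def _decode(resp):
        raw = resp.read()
        if resp.headers.get_content_type() == "application/x-hdf5":
            return raw
        if not raw:
            return None
        return json.loads(raw)


class Session:
    """High-level operations against one server."""

    def __init__(self, transport, cache: bool = True):
        self.transport = transport
        self.cache_enabled = cache
        self._cache: dict[str, tuple[str, dict]] = {}  # location -> (etag, doc)
        self.transfers = 0  # full-body responses received (cache diagnostics)

    # -- low level ---------------------------------------------------------

    def _request(self, method, path, params=None, body=None, headers=None):
        status, hdrs, payload = self.transport.request(
            method, path, params=params, body=body, headers=headers
        )
        if status >= 400:
            message = (
                payload.get("message", "") if isinstance(payload, dict) else str(payload)
            )
            if status == 412:
                raise ConflictError(status, message)
            raise ClientError(status, message)
        return status, hdrs, payload

    # -- reads ---------------------------------------------------------------

    def get(self, kind: str, object_id: str, at_time=None) -> RemoteObject:
        ns = model.NAMESPACE_OF_KIND[kind]
        path = f"/{ns}/{kind}/{object_id}/"
        params = {"at_time": at_time.isoformat()} if at_time else None
        headers = {}
        if self.cache_enabled and at_time is None and path in self._cache:
            headers["If-None-Match"] = self._cache[path][0]
        status, hdrs, doc = self._request("GET", path, params=params, headers=headers)
        if status == 304:
            doc = self._cache[path][1]
        else:
            self.transfers += 1
            if self.cache_enabled and at_time is None:
                etag = hdrs.get("ETag")
                if etag:
                    self._cache[path] = (etag, doc)
        return RemoteObject.from_document(doc)

    def select(self, kind: str, filters: Optional[dict] = None) -> list[RemoteObject]:
        """Query objects of one kind; arrays stay lazy references."""
        ns = model.NAMESPACE_OF_KIND[kind]
        params = {k: str(v) for k, v in (filters or {}).items()}
        _, _, envelope = self._request("GET", f"/{ns}/{kind}/", params=params)
        self.transfers += 1
        return [RemoteObject.from_document(d) for d in envelope["objects"]]

    # -- writes ----------------------------------------------------------------

    def save(self, obj: RemoteObject) -> RemoteObject:
        """Create (no id) or update (id present) an object.

        Updates send ``If-Match`` with the locally known e-Tag, so a stale
        copy raises :class:`ConflictError` instead of silently overwriting.
        """
        violations = model.validate_object(obj.kind, obj.fields)
        if violations:
            raise ValidationError(violations)
        ns = model.NAMESPACE_OF_KIND[obj.kind]
        body = rest.fields_to_document(obj.fields)
        if obj.id is None:
            _, _, doc = self._request("POST", f"/{ns}/{obj.kind}/", body=body)
        else:
            headers = {"If-Match": obj.etag} if obj.etag else {}
            _, _, doc = self._request(
                "POST", f"/{ns}/{obj.kind}/{obj.id}/", body=body, headers=headers
            )
        self.transfers += 1
        return RemoteObject.from_document(doc)

    def delete(self, obj: RemoteObject) -> None:
        ns = model.NAMESPACE_OF_KIND[obj.kind]
        self._request("DELETE", f"/{ns}/{obj.kind}/{obj.id}/")

    def annotate(self, obj: RemoteObject, value_ids: list[str]) -> RemoteObject:
        ns = model.NAMESPACE_OF_KIND[obj.kind]
        _, _, doc = self._request(
            "POST", f"/{ns}/{obj.kind}/{obj.id}/", body={"metadata": list(value_ids)}
        )
        return RemoteObject.from_document(doc)

    def get_acl(self, obj: RemoteObject) -> dict:
        ns = model.NAMESPACE_OF_KIND[obj.kind]
        _, _, doc = self._request("GET", f"/{ns}/{obj.kind}/{obj.id}/acl/")
        return doc

    def set_acl(self, obj: RemoteObject, acl_document: dict) -> dict:
        ns = model.NAMESPACE_OF_KIND[obj.kind]
        _, _, doc = self._request(
            "POST", f"/{ns}/{obj.kind}/{obj.id}/acl/", body=acl_document
        )
        return doc

    # -- arrays -------------------------------------------------------------

    def fetch_array(
        self,
        obj: RemoteObject,
        field: Optional[str] = None,
        window: Optional[SliceWindow] = None,
    ) -> np.ndarray:
        """Download an object's array, optionally server-sliced to a window.

        ``window`` is in canonical seconds; it is translated into
        ``start_time``/``end_time`` parameters in the units of the object's
        ``t_start`` attribute, the server computes the index bounds, and
        only the in-window samples are transferred.
        """
        if field is None:
            field = {"analogsignal": "signal", "spiketrain": "times"}.get(obj.kind)
            if field is None:
                raise ValueError(f"kind {obj.kind!r} has no default array field")
        ref = obj.fields[field]
        if isinstance(ref, model.ArrayValue):
            return np.asarray(ref.values)
        if window is None:
            return self._download(f"/datafiles/{ref.file_id}/", {})
        t_units = obj.fields["t_start"].units
        factor = model.UNIT_TABLE["time"][t_units]
        params = {
            "start_time": repr(window.start / factor),
            "end_time": repr(window.end / factor),
        }
        ns = model.NAMESPACE_OF_KIND[obj.kind]
        _, _, doc = self._request(
            "GET", f"/{ns}/{obj.kind}/{obj.id}/", params=params
        )
        array_doc = doc["fields"][field]
        if array_doc["url"] is None:
            return np.empty(0)
        url = urllib.parse.urlsplit(array_doc["url"])
        return self._download(url.path, dict(urllib.parse.parse_qsl(url.query)))

    def _download(self, path: str, params: dict) -> np.ndarray:
        _, _, payload = self._request("GET", path, params=params)
        self.transfers += 1
        with h5py.File(io.BytesIO(payload), "r") as f:
            return f["data"][()]
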