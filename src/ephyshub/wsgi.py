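"""WSGI adapter: maps real HTTP traffic onto :meth:`RestService.route_request`.

Authentication is a bearer-token stub: ``Authorization: Bearer <token>`` is
resolved to a user id through the service's identity registry; requests
without a token run as the anonymous actor (read access to public objects
only).
"""

from __future__ import annotations

import json
from http.client import responses as _reasons
from urllib.parse import parse_qsl
from wsgiref.simple_server import WSGIRequestHandler, make_server

from .rest import RestService


def _extract_headers(environ) -> dict:
    headers = {}
    for key, value in environ.items():
        if key.startswith("HTTP_"):
            headers[key[5:].replace("_", "-").title()] = value
    if "CONTENT_TYPE" in environ:
        headers["Content-Type"] = environ["CONTENT_TYPE"]
    return headers


def make_wsgi_app(service: RestService):
    def app(environ, start_response):
        method = environ["REQUEST_METHOD"]
        path = environ.get("PATH_INFO", "/")
        params = dict(parse_qsl(environ.get("QUERY_STRING", "")))
        headers = _extract_headers(environ)

        token = None
        auth = headers.get("Authorization", "")
        if auth.startswith("Bearer "):
            token = auth[len("Bearer "):].strip()
        actor = service.identity.resolve(token)

        body = None
        try:
            length = int(environ.get("CONTENT_LENGTH") or 0)
        except ValueError:
            length = 0
        if length:
            raw = environ["wsgi.input"].read(length)
            try:
                body = json.loads(raw)
            except ValueError:
                body = None

        response = service.route_request(
            method, path, params=params, body=body, headers=headers, actor=actor
        )

        if isinstance(response.body, bytes):
            payload = response.body
            content_type = response.headers.get(
                "Content-Type", "application/octet-stream"
            )
        elif response.body is None:
            payload = b""
            content_type = "application/json"
        else:
            payload = json.dumps(response.body).encode()
            content_type = "application/json"

        out_headers = [
            (k, v) for k, v in response.headers.items() if k != "Content-Type"
        ]
        out_headers.append(("Content-Type", content_type))
        out_headers.append(("Content-Length", str(len(payload))))
        reason = _reasons.get(response.status, "Unknown")
        start_response(f"{response.status} {reason}", out_headers)
        return [payload]

    return app


class _QuietHandler(WSGIRequestHandler):
    def log_message(self, *args):  # request logging happens in RestService
        pass


def serve(service: RestService, host: str = "127.0.0.1", port: int = 8000):
    """Run a blocking single-threaded development server."""
    with make_server(host, port, make_wsgi_app(service), handler_class=_QuietHandler) as srv:
        srv.serve_forever()
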