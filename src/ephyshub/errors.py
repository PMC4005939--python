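"""Exception hierarchy shared by the store, query engine and HTTP layer.

Every error that can surface through the REST interface carries an HTTP
status code so the dispatcher can translate it mechanically.
"""


class ApiError(Exception):
    """Base class for errors that map onto an HTTP response."""

    status = 500

    def __init__(self, message: str, **details):
        super().__init__(message)
        self.message = message
        self.details = details

    def to_json(self) -> dict:
        doc = {"message": self.message}
        if self.details:
            doc.update(self.details)
        return doc


class BadRequest(ApiError):
    status = 400


class Forbidden(ApiError):
    status = 403


class NotFound(ApiError):
    status = 404


class MethodNotAllowed(ApiError):
    status = 405


class Gone(ApiError):
    """Raised when writing to a soft-deleted object."""

    status = 410


class PreconditionFailed(ApiError):
    """Stale If-Match e-Tag on an optimistic-concurrency update."""

    status = 412


class UnitDimensionError(BadRequest):
    """Quantity carries units of the wrong physical dimension."""


class UnknownKindError(BadRequest):
    """Object kind is not part of the closed model."""


class ValidationError(BadRequest):
    """Object fields violate the declarative kind schema."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "validation failed: " + "; ".join(self.violations),
            violations=self.violations,
        )
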