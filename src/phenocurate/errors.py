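"""Exception hierarchy for phenocurate.

All errors raised by the library derive from :class:`PhenocurateError` so
callers can catch the whole family with one clause.  Parsing and ingestion
errors carry enough context (offending text, row/column coordinates) to be
reported back to a curator.
"""

from __future__ import annotations


class PhenocurateError(Exception):
    """Base class for all phenocurate errors."""


class MalformedIdentifierError(PhenocurateError):
    """An identifier (PMID, CURIE, ...) does not have the required shape."""


class MissingIdentifierError(PhenocurateError):
    """A required identifier is empty or absent."""


class AgeParseError(PhenocurateError):
    """An age string could not be interpreted as an ISO 8601 duration."""

    def __init__(self, text: str, reason: str = "unparseable age"):
        self.text = text
        super().__init__(f"{reason}: {text!r}")


class SchemaError(PhenocurateError):
    """A JSON document is missing a required field or has the wrong shape."""

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        super().__init__(message)


class CrossReferenceError(PhenocurateError):
    """Two elements that must agree (e.g. interpretation vs disease) do not."""


class ConfigurationError(PhenocurateError):
    """An ingest mapping or generator configuration is inconsistent."""


class CellParseError(PhenocurateError):
    """A table cell could not be converted under its column mapping."""

    def __init__(self, message: str, *, row: object = None, column: str | None = None,
                 aggregate: bool = False):
        self.row = row
        self.column = column
        #: True when the cell looks like aggregate data ("7/12"), which the
        #: corpus inclusion rule forbids at the individual level.
        self.aggregate = aggregate
        where = ""
        if row is not None or column is not None:
            where = f" (row={row!r}, column={column!r})"
        super().__init__(message + where)


class IngestError(PhenocurateError):
    """A table violates the ingest contract (e.g. duplicate row identifiers)."""


class CapacityError(PhenocurateError):
    """A corpus is too small to host the requested number of seeded violations."""
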