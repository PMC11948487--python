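"""Exception hierarchy.

All errors raised by this package derive from :class:`NeuroAuditError` so
callers can catch the whole family; the concrete classes distinguish schema
problems (missing columns, wrong layout) from semantic validation failures
(broken invariants) and bad arguments.
"""


class NeuroAuditError(Exception):
    """Base class for all package errors."""


class SchemaError(NeuroAuditError, ValueError):
    """A required column, dataset or field is missing or malformed."""


class TableValidationError(NeuroAuditError, ValueError):
    """A sample table violates a structural invariant."""


class ArgumentError(NeuroAuditError, ValueError):
    """An operation was called with arguments it cannot honour."""
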