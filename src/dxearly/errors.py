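"""Exception hierarchy shared across the package.

Domain errors (bad values) raise :class:`DomainError`, malformed documents
raise :class:`SchemaError`, dangling identifiers raise
:class:`ReferenceLookupError`, and operations on a finalized consultation
record raise :class:`FinalizedRecordError`.  All inherit from
:class:`DxEarlyError` so callers can catch the package's errors in one go.
"""

from __future__ import annotations


class DxEarlyError(Exception):
    """Base class for all errors raised by dxearly."""


class DomainError(DxEarlyError, ValueError):
    """A value is outside its documented domain (e.g. a negative incidence)."""


class SchemaError(DxEarlyError, ValueError):
    """A document does not conform to the documented schema.

    The message names the offending path and field.
    """


class ReferenceLookupError(DxEarlyError, KeyError):
    """An identifier (finding, diagnosis, reason for encounter) does not resolve."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the plain message
        return self.args[0] if self.args else ""


class FinalizedRecordError(DxEarlyError, RuntimeError):
    """A mutating operation was attempted on a finalized consultation record."""


class FitError(DxEarlyError, RuntimeError):
    """A statistical fit failed (separation, singular design, non-convergence)."""
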