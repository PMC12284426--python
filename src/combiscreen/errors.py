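"""Exception hierarchy for combiscreen.

All package errors derive from :class:`CombiScreenError` so callers can catch
one base class; subclasses also derive from the closest builtin (``ValueError``
for bad values, ``KeyError``-like lookups stay ``ValueError`` for message
clarity).
"""


class CombiScreenError(Exception):
    """Base class for all combiscreen errors."""


class SchemaError(CombiScreenError, ValueError):
    """An input table is missing required columns or has a malformed layout."""


class ValidationError(CombiScreenError, ValueError):
    """A record violates a domain invariant (names the offending row/field)."""


class DegenerateControlError(CombiScreenError, ValueError):
    """Control signal does not exceed background; normalization undefined."""


class InsufficientDataError(CombiScreenError, ValueError):
    """Too few points/records for the requested computation."""


class DegenerateSignalError(CombiScreenError, ValueError):
    """Signal statistics are degenerate (e.g. non-positive mean for CV)."""


class NonConvergenceError(CombiScreenError, RuntimeError):
    """A curve fit could not converge; carries diagnostics in ``details``."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class ConfigurationError(CombiScreenError, ValueError):
    """Invalid or inconsistent configuration (missing fit, bad target, ...)."""


class UnitError(CombiScreenError, ValueError):
    """Incompatible or unknown units where a conversion is required."""


class DomainError(CombiScreenError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class UndefinedTestError(CombiScreenError, ValueError):
    """A statistical test is undefined for the given data (e.g. no events)."""
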