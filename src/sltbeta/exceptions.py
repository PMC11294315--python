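"""Exception hierarchy.

All package errors derive from :class:`SltBetaError` so callers can catch
one type; the subclasses distinguish schema problems in tabular input,
value-level validation failures, and numerical degeneracies in the
truncated-beta machinery.
"""


class SltBetaError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(SltBetaError, ValueError):
    """A required column is missing or the file layout is wrong."""


class ValidationError(SltBetaError, ValueError):
    """Data values violate a documented invariant (bounds, ordering, ...)."""


class NumericalDegeneracyError(SltBetaError, ArithmeticError):
    """The truncation mass of the SLT beta law underflowed to zero.

    Raised instead of silently returning ``-inf`` so that optimizer
    failures are attributable.
    """
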