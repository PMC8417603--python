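"""Exception hierarchy for ineqkit.

All errors raised by the library derive from :class:`IneqkitError`, so
callers (and the CLI) can distinguish library failures from genuine bugs.
Input-shaped problems subclass ``ValueError``/``TypeError`` as appropriate
so that idiomatic ``except ValueError`` handling still works.
"""


class IneqkitError(Exception):
    """Base class for all ineqkit errors."""


class EmptyInputError(IneqkitError, ValueError):
    """Raised when a distribution would be empty (e.g. all entries missing)."""


class NegativeValueError(IneqkitError, ValueError):
    """Raised when negative units are present and the policy forbids them."""


class NonNumericError(IneqkitError, TypeError):
    """Raised when units cannot be interpreted as numbers."""


class DomainError(IneqkitError, ValueError):
    """Raised when a measure is undefined for the supplied input or parameter.

    Examples: the corrected Gini at k = 1, the Simpson index at N < 2,
    generalized entropy with non-positive alpha on zero units.
    """


class CurveKindError(IneqkitError, TypeError):
    """Raised when a curve-geometry function receives the wrong curve kind."""


class ConsistencyError(IneqkitError, ArithmeticError):
    """Raised when two routes to the same quantity disagree beyond tolerance.

    Used by the Atkinson/generalized-entropy conversion to surface
    transcription or parameterisation mistakes instead of returning a
    silently wrong number.
    """
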