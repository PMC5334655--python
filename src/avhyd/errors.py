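"""Exception hierarchy shared across the package."""


class AvhydError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(AvhydError, ValueError):
    """A parameter or landmark set violates its invariants."""


class InfeasibleAnchorError(InvalidParameterError):
    """The crossover anchor cannot be satisfied by the supplied landmarks."""


class GenerationError(AvhydError, RuntimeError):
    """Subject generation failed to satisfy invariants within the redraw cap."""


class DomainError(AvhydError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class DegenerateSampleError(DomainError):
    """All paired differences are zero; the signed-rank test is undefined."""


class UnsupportedSizeError(DomainError):
    """Effective sample size exceeds the exact-enumeration limit."""


class SchemaError(AvhydError, ValueError):
    """A CSV/JSON document does not conform to the expected schema."""


class NumericalFailureError(AvhydError, RuntimeError):
    """The integrator produced a non-finite state."""
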