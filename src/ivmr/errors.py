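"""Exception hierarchy for ivmr."""


class IvmrError(Exception):
    """Base class for all ivmr errors."""


class ConfigurationError(IvmrError, ValueError):
    """Invalid configuration: missing columns, bad flags, empty grids."""


class ParseError(IvmrError, ValueError):
    """Malformed input rows; carries the offending line numbers."""

    def __init__(self, message: str, lines: list[int] | None = None):
        super().__init__(message)
        self.lines = lines or []


class InsufficientInstrumentsError(IvmrError, ValueError):
    """Fewer instruments than the estimator requires."""


class WeakInstrumentError(IvmrError, ValueError):
    """An exposure beta of exactly zero makes the Wald ratio undefined."""


class DomainError(IvmrError, ValueError):
    """A numeric argument outside its mathematical domain."""


class ComplexityError(IvmrError, ValueError):
    """Problem size exceeds what exhaustive enumeration supports."""


class EstimationError(IvmrError, RuntimeError):
    """Numerical failure inside an estimator (singular fit, zero variance)."""
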