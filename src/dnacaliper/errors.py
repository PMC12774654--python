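"""Exception hierarchy shared across the package."""


class DncError(Exception):
    """Base class for all package-specific errors."""


class DomainError(DncError, ValueError):
    """Input outside the mathematical domain of an operation."""


class ArgumentError(DncError, ValueError):
    """Structurally invalid argument (empty list, bad shape, ...)."""


class PreconditionError(DncError, ValueError):
    """A documented precondition of an analysis step was violated."""


class FitError(DncError, RuntimeError):
    """A fit could not be performed (degenerate data, rank deficiency)."""


class FormatError(DncError, ValueError):
    """Malformed input file."""


class ConfigurationError(DncError, ValueError):
    """Inconsistent run configuration or preset."""


class AxisAmbiguityError(DncError, ValueError):
    """An observed unlooping length falls inside two axis windows."""
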