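"""Exception types shared across the package."""


class PagsemError(Exception):
    """Base class for package errors."""


class ConfigError(PagsemError, ValueError):
    """Invalid configuration value; ``field`` names the offending entry."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class DomainError(PagsemError, ValueError):
    """Input outside the mathematical domain of an operation."""


class NumericalError(PagsemError, ArithmeticError):
    """A computation produced non-finite or singular results."""


class ConvergenceError(PagsemError, RuntimeError):
    """An iterative procedure failed to converge when convergence is required."""
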