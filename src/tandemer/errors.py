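"""Exception hierarchy.

Validation problems (bad input files, inconsistent models, out-of-range
arguments) and numerical problems (singular cluster systems, non-converged
fixed points) are kept distinct so the CLI can map them to exit codes 1 and 2.
"""


class TandemerError(Exception):
    """Base class for all package errors."""


class ValidationError(TandemerError):
    """Invalid user input: arguments, files, or model inconsistencies."""


class ParseError(ValidationError):
    """A model/CSV file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ModelError(ValidationError):
    """A structurally invalid network (untracked influx atom, no producer, ...)."""


class NumericalError(TandemerError):
    """A numerical failure while solving balance systems."""


class SingularSystemError(NumericalError):
    """A cluster flux matrix is singular or numerically rank deficient."""


class ConvergenceError(NumericalError):
    """The brute-force fixed-point iteration did not reach tolerance."""
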