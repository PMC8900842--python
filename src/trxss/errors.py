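"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (config 2, validation 3, fit failure 4);
library users catch them like ordinary ValueErrors.
"""


class TRXSSError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(TRXSSError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(TRXSSError, ValueError):
    """A curve or scan file does not follow the documented text format."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ValidationError(TRXSSError, ValueError):
    """A domain object violates its invariants (e.g. broken step alternation)."""


class DegenerateInputError(TRXSSError, ValueError):
    """Numerically degenerate input (zero normalisation integral, zero basis...)."""


class OutOfDomainError(TRXSSError, ValueError):
    """A query point lies outside an interpolated field's domain."""


class FitFailureError(TRXSSError, RuntimeError):
    """A nonlinear fit failed to converge from every starting point."""


class ConfigError(TRXSSError, ValueError):
    """A pipeline configuration is incomplete or inconsistent."""
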