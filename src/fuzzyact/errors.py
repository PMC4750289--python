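"""Exception hierarchy shared across the package."""


class FuzzyactError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FuzzyactError, ValueError):
    """Invalid membership-function or configuration parameters."""


class ParseError(FuzzyactError, ValueError):
    """Malformed FCL-style rule file.

    Carries the 1-based source line where the problem was detected.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InputError(FuzzyactError, ValueError):
    """Invalid crisp inputs, missing variables, or malformed records."""


class DegenerateInputError(InputError):
    """Input data carries no usable signal (e.g. constant expression)."""


class FormatError(FuzzyactError, ValueError):
    """Malformed tabular input file."""


class FitError(FuzzyactError, RuntimeError):
    """Model fit failed or degenerated (e.g. vanishing mixture component)."""
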