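"""Exception hierarchy shared across trhkit modules."""


class TrhError(Exception):
    """Base class for all trhkit errors."""


class FormatError(TrhError):
    """A file does not conform to its expected dialect."""


class ParseError(FormatError):
    """A specific line or record could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(TrhError):
    """Parsed data violates a structural invariant."""


class ParameterError(TrhError):
    """A user-supplied parameter is outside its valid range."""


class ConfigurationError(TrhError):
    """Inputs are mutually inconsistent (e.g. catalog/chain assembly mismatch)."""


class GenerationError(TrhError):
    """A synthetic fixture specification cannot be realised."""
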