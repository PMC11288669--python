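"""Exception types shared across the package."""


class EigenchoiceError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EigenchoiceError, ValueError):
    """A configuration object failed validation.

    Carries the name of the offending field so callers (and error
    messages) can point at it directly.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class DataError(EigenchoiceError, ValueError):
    """Input data violated a structural precondition (shape, sign, ids)."""
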