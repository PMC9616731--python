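"""Exception types shared across the pipeline."""


class WinshiftError(Exception):
    """Base class for all package errors."""


class ValidationError(WinshiftError, ValueError):
    """Raised when input data violate a documented invariant."""


class EmptyBoutError(ValidationError):
    """Raised when a bout to be scored contains no arm visits."""


class DesignError(ValidationError):
    """Raised when bouts do not match the requested testing design."""


class SchemaError(ValidationError):
    """Raised when a CSV/JSON artifact is missing required structure."""
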