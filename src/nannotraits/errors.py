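"""Exception hierarchy shared across the package."""


class NannotraitsError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NannotraitsError):
    """A table is missing a required column or has an unusable layout."""


class RowValidationError(NannotraitsError):
    """A row violates a domain invariant (carries the offending row index)."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class InsufficientDataError(NannotraitsError):
    """Too few usable observations for the requested operation."""


class DegenerateFitError(NannotraitsError):
    """A regression cannot be identified (e.g. zero predictor variance)."""


class ConfigurationError(NannotraitsError):
    """Inconsistent or incomplete model configuration."""


class DomainError(NannotraitsError, ValueError):
    """A numeric argument is outside the physically meaningful domain."""
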