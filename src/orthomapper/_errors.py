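"""Exception and warning types shared across the package."""


class OrthomapperError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OrthomapperError):
    """Invalid inputs: bad shapes, mismatched identifiers, broken invariants."""


class DialectError(ValidationError):
    """A mapping-table file does not conform to the declared dialect."""


class NoFeaturesMappedError(OrthomapperError):
    """Raised when not a single feature of a matrix has an ortholog target.

    Carries the (zero) gene mapping rate so callers can report it.
    """

    def __init__(self, message: str, mapping_rate: float = 0.0):
        super().__init__(message)
        self.mapping_rate = mapping_rate


class ConversionWarning(UserWarning):
    """Non-fatal condition noticed during conversion or QC."""
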