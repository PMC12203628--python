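"""Exception hierarchy shared across the package."""


class SwperGeoError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(SwperGeoError):
    """A population spec violates its invariants (counts, variances, rates)."""


class FixtureParseError(SwperGeoError):
    """A fixture file is malformed; carries the offending line when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class SchemaError(SwperGeoError):
    """Required columns or flags are missing from an input table."""


class DataError(SwperGeoError):
    """A record carries a value that cannot be recoded or scored."""


class CodebookError(SwperGeoError):
    """The item codebook is invalid or lacks required provenance."""


class DegenerateDistributionError(SwperGeoError):
    """A score distribution has zero spread and cannot be standardised."""


class NestingViolationError(SwperGeoError):
    """A unit appears under more than one parent in the hierarchy."""


class SeparationError(SwperGeoError):
    """The binary outcome is constant; the intercept is not identified."""


class UndefinedVpcError(SwperGeoError):
    """All geographic variances are zero; the partition is undefined."""


class LineageError(SwperGeoError):
    """A community in the index has no matching unit in the model fit."""


class MappingError(SwperGeoError):
    """A child geometry has no parent in the dissolve mapping."""


class InsufficientDataError(SwperGeoError):
    """Too few usable units for the requested statistic."""
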