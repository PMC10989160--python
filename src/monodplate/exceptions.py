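"""Exception hierarchy for the monodplate pipeline.

All errors raised by this package derive from :class:`MonodPlateError` so
callers can catch pipeline failures without masking programming errors.
"""


class MonodPlateError(Exception):
    """Base class for all monodplate errors."""


class SchemaError(MonodPlateError):
    """An input table is missing a required column or has an unusable dtype."""


class ValidationError(MonodPlateError):
    """Parsed data violate a structural invariant (e.g. nonpositive RFU)."""


class InsufficientDataError(MonodPlateError):
    """Too few observations to perform the requested computation."""


class SingularFitError(MonodPlateError):
    """A regression design is degenerate (e.g. all time points identical)."""


class DomainError(MonodPlateError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class UndefinedRStarError(DomainError):
    """R* does not exist: mu_max <= D, the strain cannot persist at dilution D."""


class ConfigurationError(MonodPlateError):
    """A run configuration is incomplete or inconsistent."""


class DegenerateRegressionError(MonodPlateError):
    """A regression cannot be computed (zero variance in the predictor)."""
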