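"""Exception hierarchy used across the package."""


class TrialKitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TrialKitError, ValueError):
    """Invalid configuration (probabilities out of range, nonpositive rates, ...)."""


class ValidationError(TrialKitError, ValueError):
    """Input data violates a documented precondition."""


class EmptyInputError(ValidationError):
    """An operation received no usable records."""


class ExtrapolationError(ValidationError):
    """A summary was requested beyond the observed follow-up."""


class IdentifiabilityError(TrialKitError):
    """Model parameters are not identifiable from the data (e.g. an arm with no events)."""
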