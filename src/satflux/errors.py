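"""Exception types shared across the package."""


class SatfluxError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SatfluxError, ValueError):
    """An input value violates a documented precondition.

    The message names the offending field or argument.
    """


class ConfigurationError(SatfluxError):
    """A configuration is internally inconsistent or incomplete."""


class DegenerateDataError(SatfluxError):
    """Data carry no information about the model being fitted."""


class ConditioningWarning(UserWarning):
    """A fit was started from a degenerate / ill-conditioned configuration."""
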