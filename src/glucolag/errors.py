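"""Exception hierarchy shared across the package."""


class GlucolagError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(GlucolagError, ValueError):
    """A value passed to an operation violates its preconditions."""


class ConfigurationError(GlucolagError, ValueError):
    """A configuration object or file is inconsistent or incomplete."""


class ParseError(GlucolagError, ValueError):
    """A data file could not be parsed; the message names the offending line."""


class NoFeatureError(GlucolagError, ValueError):
    """A time series lacks the non-constant feature an estimator needs."""


class FitError(GlucolagError, RuntimeError):
    """Every candidate in a model fit failed."""
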