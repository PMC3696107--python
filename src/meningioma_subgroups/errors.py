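"""Exception hierarchy shared across the package."""


class MeningiomaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MeningiomaError, ValueError):
    """A configuration value is invalid; the message names the field."""


class InsufficientDataError(MeningiomaError, ValueError):
    """Too few observations to carry out the requested computation."""


class RangeError(MeningiomaError, ValueError):
    """A requested interval falls outside the data it indexes."""


class UnclassifiableError(MeningiomaError, ValueError):
    """A sample lacks every evidence stream needed for classification."""
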