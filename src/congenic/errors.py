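"""Exception hierarchy shared across the package."""


class CongenicError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(CongenicError, ValueError):
    """Input data violates a documented contract (bad values, duplicates, ...)."""


class FormatError(CongenicError, ValueError):
    """A file does not conform to the expected tab-separated dialect."""


class ConfigurationError(CongenicError, ValueError):
    """An analysis was requested with inconsistent or missing configuration."""
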