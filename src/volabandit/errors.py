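"""Exception hierarchy shared across the package."""


class VolabanditError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VolabanditError, ValueError):
    """A configuration object is internally inconsistent.

    The message names the offending field.
    """


class ParseError(VolabanditError, ValueError):
    """A trial or questionnaire file could not be parsed.

    The message carries the offending row number where applicable.
    """


class ValidationError(VolabanditError, ValueError):
    """Inputs violate an operation's preconditions."""
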