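"""Exception hierarchy shared by all modules."""


class MetapeptError(Exception):
    """Base class for all package errors."""


class FormatError(MetapeptError):
    """An input file does not conform to its declared dialect."""


class ValueParseError(MetapeptError):
    """A cell could not be converted to the expected type."""


class ConfigurationError(MetapeptError):
    """A run/filter configuration is internally inconsistent."""


class UsageError(MetapeptError):
    """An operation was applied to a table of the wrong kind or level."""


class NormalizationError(MetapeptError):
    """A sample column cannot be renormalized (all-missing or zero-sum)."""
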