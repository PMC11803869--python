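"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigurationError -> 2, DataError -> 3.
"""


class NucposError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NucposError):
    """Invalid options, incompatible inputs to an operation, bad config files."""


class DataError(NucposError):
    """Unreadable, empty or malformed data."""
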