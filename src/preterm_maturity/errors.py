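"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigurationError -> 2, DataError -> 3.
"""


class PretermMaturityError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PretermMaturityError):
    """An invalid parameter or configuration value; names the offending field."""


class DataError(PretermMaturityError):
    """Malformed or inconsistent input data; carries row/column context."""
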