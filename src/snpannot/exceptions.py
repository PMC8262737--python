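"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class SnpAnnotError(Exception):
    """Base class for all package errors."""


class ConfigError(SnpAnnotError):
    """Invalid configuration or invalid arguments to an operation."""


class DataError(SnpAnnotError):
    """Malformed, inconsistent or unresolvable input data."""


class FormatError(DataError):
    """A file whose structure (not just a single row) cannot be interpreted."""
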