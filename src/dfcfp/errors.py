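"""Exception hierarchy shared across the package.

The command-line interface maps these onto exit codes:
``ConfigError`` -> 2, ``DataError`` -> 3, ``NumericalError`` -> 4.
"""


class DfcfpError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DfcfpError):
    """Invalid parameters, bounds, or configuration."""


class DataError(DfcfpError):
    """Malformed, inconsistent, or incompatible input data."""


class NumericalError(DfcfpError):
    """A computation failed or its result is undefined."""
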