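"""Exception hierarchy.

ConfigError maps to CLI exit code 2, DataError to exit code 3.
"""


class SelsigError(Exception):
    """Base class for package errors."""


class ConfigError(SelsigError):
    """Invalid or inconsistent run configuration."""


class DataError(SelsigError):
    """Invalid, inconsistent or insufficient input data."""


class VcfParseError(DataError):
    """Malformed VCF input; message names the offending file/record."""
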