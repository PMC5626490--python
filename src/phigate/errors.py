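"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class PhigateError(Exception):
    """Base class for all package errors."""


class ConfigError(PhigateError):
    """Invalid configuration or parameter values."""


class DataError(PhigateError):
    """Input data that cannot be analyzed (degenerate, missing, corrupt)."""
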