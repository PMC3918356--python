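"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class CordFAError(Exception):
    """Base class for all package errors."""


class ConfigError(CordFAError):
    """Invalid configuration: bad parameter values, malformed config files."""


class DataError(CordFAError):
    """Invalid data: schema mismatches, empty masks, degenerate tables."""
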