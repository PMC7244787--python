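"""Exception hierarchy.

All package errors derive from :class:`SmurfError` so callers can catch one
type; the subclasses map onto the CLI exit codes (config error, data error).
"""


class SmurfError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(SmurfError, ValueError):
    """Invalid hyper-parameters, fold counts, or run configuration."""


class DataFormatError(SmurfError, ValueError):
    """Malformed or inconsistent input files / arrays."""


class MetricUndefinedError(SmurfError, ValueError):
    """Requested metric is undefined for the given labels (single class)."""


class ModelIOError(SmurfError, IOError):
    """Model archive missing, corrupt, or of an incompatible version."""
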