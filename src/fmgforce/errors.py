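"""Labeled error types shared across the package.

Configuration problems (bad parameter values, impossible protocol settings)
raise :class:`ConfigError`; problems with the data itself (shape mismatches,
missing sidecars, degenerate inputs) raise :class:`DataError`.  The CLI maps
these to exit codes 2 and 3 respectively.
"""


class FmgError(ValueError):
    """Base class for labeled errors raised by fmgforce."""


class ConfigError(FmgError):
    """Invalid configuration: parameter values outside their allowed range."""


class DataError(FmgError):
    """Invalid or inconsistent data: shapes, files, masks, degenerate inputs."""
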