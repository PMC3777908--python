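"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class TQCouplingError(Exception):
    """Base class for all package errors."""


class ConfigError(TQCouplingError):
    """Invalid configuration or parameters."""

    exit_code = 2


class DataError(TQCouplingError):
    """Invalid, inconsistent or degenerate input data."""

    exit_code = 3


class DegenerateGeometryError(DataError):
    """Point cloud too degenerate to define a rigid superposition."""


class UnknownElementError(DataError):
    """An atom has an element symbol missing from the parameter tables."""
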