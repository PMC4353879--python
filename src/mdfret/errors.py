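"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to
exit code 3.
"""


class MdFretError(Exception):
    """Base class for all package errors."""


class ConfigError(MdFretError):
    """Invalid or inconsistent run configuration."""


class DataError(MdFretError):
    """Invalid input data (files, tables, geometries)."""


class DegenerateGeometryError(DataError):
    """Zero-length separation or dipole vector."""


class InsufficientDataError(DataError):
    """Too few frames (or spectrum points) to compute the requested quantity."""


class SiteResolutionError(DataError):
    """A configured site atom could not be resolved uniquely in the topology."""


class NormalizationError(DataError):
    """Spectrum cannot be normalized (zero integral)."""


class ChargePatchError(DataError):
    """Charge-delta table inconsistent with the base charge table."""
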