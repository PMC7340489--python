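"""Exception hierarchy for parcelscope."""


class ParcelscopeError(Exception):
    """Base class for all parcelscope errors."""


class ConfigError(ParcelscopeError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(ParcelscopeError):
    """A file or record does not satisfy the expected schema (e.g. a missing band role)."""


class UnsupportedCRSError(ParcelscopeError):
    """Raster uses a geographic (unprojected) coordinate reference system."""


class IncompatibleTilesError(ParcelscopeError):
    """Tiles differ in CRS, band count or pixel size and cannot be mosaicked."""


class AlignmentError(ParcelscopeError):
    """Raster grids are not co-aligned (origins differ by non-integer pixel multiples)."""


class InsufficientDataError(ParcelscopeError):
    """Too few observations for the requested model."""


class DegeneracyError(ParcelscopeError):
    """Degenerate geometry (e.g. collinear tie points for an affine fit, or a field
    with no valid co-occurrence pairs)."""
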