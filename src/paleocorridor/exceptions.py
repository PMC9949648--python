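"""Exception hierarchy shared across the package."""


class PaleocorridorError(Exception):
    """Base class for all package errors."""


class GridFormatError(PaleocorridorError):
    """A raster file violates its dialect (bad header field, non-square cells...)."""


class AlignmentError(PaleocorridorError):
    """Two grids that must share geometry do not, or extents fail to overlap."""


class ParameterError(PaleocorridorError):
    """A numeric parameter is out of its valid range (inverted band, k<0...)."""


class GeometryError(PaleocorridorError):
    """An input polygon is invalid (self-intersecting, unclosed...)."""


class PlacementError(PaleocorridorError):
    """A route endpoint falls off-grid or on a non-traversable cell."""


class UnreachableError(PaleocorridorError):
    """No finite-cost route exists between the endpoints (absolute barrier)."""


class GenerationError(PaleocorridorError):
    """Synthetic-landscape parameters produce an unusable fixture."""


class ConfigError(PaleocorridorError):
    """A run configuration is inconsistent (unknown site name, missing input)."""
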