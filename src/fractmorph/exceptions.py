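"""Exception hierarchy used across the pipeline."""


class FractmorphError(Exception):
    """Base class for all package errors."""


class ImageInputError(FractmorphError, ValueError):
    """Unreadable, empty, or otherwise invalid raster input."""


class EmptyMeasureError(FractmorphError, ValueError):
    """An operation that needs mass received an all-zero field/image."""


class InsufficientDataError(FractmorphError, ValueError):
    """Too few data points for the requested fit or summary."""


class ConfigError(FractmorphError, ValueError):
    """Invalid analysis configuration (grids, stages, windows)."""


class GridMismatchError(ConfigError):
    """Two results were computed on incompatible q-grids or box ladders."""
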