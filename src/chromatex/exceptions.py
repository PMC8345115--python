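"""Exception hierarchy shared across the package."""


class ChromatexError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChromatexError, ValueError):
    """Input file does not conform to the expected format (e.g. missing column)."""


class ParseError(ChromatexError, ValueError):
    """A value in an input file could not be parsed; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class GeometryError(ChromatexError, ValueError):
    """Invalid or degenerate geometry (polygon, endpoints, ...)."""


class ParameterError(ChromatexError, ValueError):
    """Invalid parameter value passed to an operation."""


class EmptyInputError(ChromatexError, ValueError):
    """An operation that needs at least one element received none."""


class SegmentationError(ChromatexError, RuntimeError):
    """Image segmentation failed to find any foreground."""


class ConsistencyError(ChromatexError, RuntimeError):
    """Internal consistency violated (e.g. domain area exceeds nuclear area)."""


class PlacementError(ChromatexError, RuntimeError):
    """Synthetic objects could not be placed without overlap."""


class RingWarning(UserWarning):
    """Non-fatal geometry caveat for radial ring construction."""
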