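"""Exception types shared across the pipeline."""


class FlickerscopeError(Exception):
    """Base class for package errors."""


class DegenerateInputError(FlickerscopeError):
    """Input carries no usable signal (constant frame, zero-variance series, ...)."""


class SpecValidationError(FlickerscopeError):
    """A generator or run specification violates its preconditions."""


class NonStarConvexError(FlickerscopeError):
    """Component boundary is multi-valued in polar form about its centroid."""


class TrackingError(FlickerscopeError):
    """Video tracking failed; carries the offending frame index."""

    def __init__(self, frame_index: int, message: str):
        super().__init__(f"frame {frame_index}: {message}")
        self.frame_index = frame_index


class UnusableCellError(FlickerscopeError):
    """Too many degenerate angle series to summarize a cell."""


class SchemaError(FlickerscopeError):
    """A table is missing required columns."""
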