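"""Exception hierarchy for the pipeline.

Every error raised by tissuemux derives from :class:`TissuemuxError` so callers
can catch pipeline failures without masking programming errors.
"""


class TissuemuxError(Exception):
    """Base class for all tissuemux errors."""


class FormatError(TissuemuxError):
    """Malformed input file (missing columns, duplicate coordinates...)."""


class MetadataMismatchError(TissuemuxError):
    """Channel metadata does not match the supplied images or text headers."""


class ShapeError(TissuemuxError):
    """Image dimensions are inconsistent."""


class StateError(TissuemuxError):
    """Operation applied to an object in the wrong state (e.g. re-normalising)."""


class DegenerateInputError(TissuemuxError):
    """Input has too little structure for the operation (e.g. constant channel)."""


class RecipeError(TissuemuxError):
    """A mask recipe references an unknown source or contains an invalid step."""


class ParameterError(TissuemuxError):
    """Invalid or missing parameter value."""


class IntegrityError(TissuemuxError):
    """Internal consistency violation (e.g. gap in a label image)."""


class ConfigurationError(TissuemuxError):
    """Invalid run configuration."""


class ExpressionError(TissuemuxError):
    """Failure to parse or evaluate a boolean marker/mask expression."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class GenerationError(TissuemuxError):
    """Synthetic-tissue generation could not satisfy the requested spec."""


class UndefinedFractionError(TissuemuxError):
    """Pixel-area fraction requested over an empty denominator mask."""
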