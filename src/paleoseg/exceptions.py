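"""Exception hierarchy for the segmentation pipeline.

Every stage raises a subclass of :class:`PaleosegError` so callers (and the
CLI) can distinguish user-input problems from genuine bugs.
"""


class PaleosegError(Exception):
    """Base class for all pipeline errors."""


class MissingInputError(PaleosegError):
    """No input files matched, or a required artifact is absent."""


class GeometryError(PaleosegError):
    """Slice/mask/crop dimensions are inconsistent."""


class FormatError(PaleosegError):
    """Unsupported image format, bit depth, or channel layout."""


class NotBinaryError(FormatError):
    """A mask image contains more than two distinct pixel values."""


class ConstructionError(PaleosegError):
    """Phantom geometry too small for the requested structures."""


class RefinementError(PaleosegError):
    """Annotation plan cannot be refined (e.g. odd stride)."""


class InsufficientAnnotationError(PaleosegError):
    """Too few annotated slices for the requested operation."""


class SamplingError(PaleosegError):
    """Crop sampling cannot proceed (e.g. no negative ranges declared)."""


class ScheduleError(PaleosegError):
    """An epoch schedule cannot be built (no training slices)."""


class TrainingDivergenceError(PaleosegError):
    """Loss became non-finite during training."""

    def __init__(self, epoch: int, message: str = ""):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class CoverageError(PaleosegError):
    """Requested slice indices lack reference masks."""


class ConfigurationError(PaleosegError):
    """Inconsistent run configuration (channels, thresholds, paths)."""


class PipelineStateError(PaleosegError):
    """A pipeline stage is missing a prerequisite artifact."""
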