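"""Exception hierarchy for the grading pipeline.

Each pipeline stage raises a distinct error type so that callers (and the
CLI, which maps them to exit codes) can tell which stage failed.
"""


class KneegradeError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(KneegradeError, ValueError):
    """A parameter violates its documented precondition."""


class DegenerateInputError(KneegradeError, ValueError):
    """Input is structurally valid but degenerate (e.g. all-zero image)."""


class InvalidStateError(KneegradeError, RuntimeError):
    """An object is used before a required computation step."""


class ROINotFoundError(KneegradeError, RuntimeError):
    """The joint-space region could not be located (no two bone bands)."""


class SegmentationFailedError(KneegradeError, RuntimeError):
    """Active-contour segmentation produced no usable foreground."""
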