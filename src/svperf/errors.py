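"""Exception hierarchy for the perfusion pipeline.

Every stage raises a subclass of :class:`SvperfError` so callers (and the
CLI) can distinguish protocol failures from bad inputs.
"""


class SvperfError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SvperfError, ValueError):
    """A model or configuration parameter is non-finite or out of range."""


class ProtocolFailureError(SvperfError, RuntimeError):
    """The simulated acquisition never reached the bolus-tracking trigger.

    Mirrors the false-triggering exclusion applied to real acquisitions in
    which the tracking ROI never crosses the 80-HU threshold.
    """


class NoEnhancementError(SvperfError, ValueError):
    """Aortic or myocardial samples never rise above baseline."""


class InsufficientBaselineError(SvperfError, ValueError):
    """Fewer pre-arrival bolus-tracking frames than requested."""


class EmptySegmentationError(SvperfError, ValueError):
    """A mask meant to delineate tissue contains no voxels."""


class ShapeMismatchError(SvperfError, ValueError):
    """Volume and mask grids are not congruent."""


class DegenerateRegressionError(SvperfError, ValueError):
    """Paired regression requested on a constant predictor."""


class UndefinedCorrelationError(SvperfError, ValueError):
    """Rank correlation undefined because one margin is entirely tied."""


class StageError(SvperfError, RuntimeError):
    """Wraps an error from a pipeline stage with a stage label."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}': {original}")
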