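"""Exception hierarchy.

Every error raised by the library derives from :class:`TmtvError`, so callers
(and the CLI) can distinguish configuration problems from data problems.
"""


class TmtvError(Exception):
    """Base class for all tmtvkit errors."""


class InvalidMetadataError(TmtvError):
    """Injection metadata with non-positive dose, weight, interval or half-life."""


class OutOfBoundsError(TmtvError):
    """A geometric primitive was requested at a point outside the image grid."""


class EmptyRegionError(TmtvError):
    """A region (mask, cylinder, ROI) is empty where a non-empty one is required."""


class UnreliableReferenceError(TmtvError):
    """Blood-pool reference region contains too few voxels for stable statistics."""


class GridMismatchError(TmtvError):
    """Two volumes/masks that must share a grid do not."""


class CollisionError(TmtvError):
    """Overlapping synthetic lesion specifications."""


class DegenerateDataError(TmtvError):
    """Input data cannot support the requested estimate (no events, one class, ...)."""


class InsufficientDataError(TmtvError):
    """Too few observations for the requested statistic."""


class UndefinedStatisticError(TmtvError):
    """The statistic is mathematically undefined on this input (e.g. zero rank variance)."""


class ConvergenceError(TmtvError):
    """An iterative fit failed to converge (e.g. monotone partial likelihood)."""
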