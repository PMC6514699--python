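"""Exception hierarchy for the leafgeom pipeline.

Every stage raises a subclass of :class:`LeafGeomError`; the top-level
``measure`` driver re-raises them tagged with the pipeline stage that
failed so batch runs can report per-image failure causes.
"""


class LeafGeomError(Exception):
    """Base class for all leafgeom errors."""

    #: pipeline stage label, filled in by the measurement driver
    stage: str | None = None


class InvalidInputError(LeafGeomError):
    """Input image/contour does not satisfy an operation's preconditions."""


class InvalidParameterError(LeafGeomError):
    """A configuration parameter is outside its documented range."""


class DegenerateImageError(LeafGeomError):
    """Image has no intensity structure (e.g. constant under Otsu)."""


class PlateNotFoundError(LeafGeomError):
    """No contour simplifiable to a convex quadrilateral was found."""


class SingularSystemError(LeafGeomError):
    """Homography system is singular (degenerate corner geometry)."""


class SceneInvalidError(LeafGeomError):
    """Mask does not contain the expected frame + leaf components."""


class ScaleUnreadableError(LeafGeomError):
    """Too few tick marks recovered to derive a physical scale."""


class OutOfRangeError(LeafGeomError):
    """Bounding rectangle extends beyond the tick-covered span."""


class InvalidStatsError(LeafGeomError):
    """Pixel-count statistics are degenerate (zero denominators)."""


class InvalidSpecError(LeafGeomError):
    """Synthetic scene specification is geometrically impossible."""


def tag_stage(exc: LeafGeomError, stage: str) -> LeafGeomError:
    """Attach a pipeline stage label to an error and return it."""
    exc.stage = stage
    if stage not in str(exc):
        exc.args = (f"[{stage}] " + (str(exc.args[0]) if exc.args else ""),)
    return exc
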