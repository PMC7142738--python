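"""Exception hierarchy for the food-volumetry pipeline.

Every stage raises a subclass of :class:`FoodvolError` so callers can
attribute a failure to the stage that produced it.
"""


class FoodvolError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FoodvolError):
    """Inconsistent inputs (shape mismatch, bad parameters, empty pools)."""


class EmptyCloudError(FoodvolError):
    """A depth map contained no valid pixels."""


class PlaneFitError(FoodvolError):
    """RANSAC could not fit a plane (too few or collinear points)."""


class TriangulationError(FoodvolError):
    """Surface triangulation failed (fewer than 3 points)."""


class RenderError(FoodvolError):
    """Ray-cast rendering produced no valid scene geometry in the frustum."""


class UndefinedMetricError(FoodvolError):
    """A segmentation metric is undefined (empty reference region)."""


class FoodLookupError(FoodvolError):
    """Unknown food identifier in a density/composition table."""


class TableValidationError(FoodvolError):
    """A food table violated its schema or invariants."""
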