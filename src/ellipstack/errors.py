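"""Exception hierarchy for ellipstack.

All errors derive from :class:`EllipstackError` so callers can catch the
package's failures with one clause.  Input-validation problems additionally
derive from :class:`ValueError` to behave like ordinary Python misuse.
"""


class EllipstackError(Exception):
    """Base class for all ellipstack errors."""


class InvalidParameterError(EllipstackError, ValueError):
    """A parameter is outside its documented domain (e.g. non-positive axis)."""


class InsufficientDataError(EllipstackError, ValueError):
    """Too few data points for the requested operation (e.g. < 5 for a fit)."""


class DegenerateContourError(EllipstackError, ValueError):
    """Contour points are collinear/degenerate or admit no elliptical fit."""


class DegenerateControlPointsError(EllipstackError, ValueError):
    """Control points are coincident or otherwise define no valid transform."""


class ShapeMismatchError(EllipstackError, ValueError):
    """Stacks/models with incompatible slice counts were combined."""


class GeometryError(EllipstackError, ValueError):
    """Inconsistent image geometry (orientation, slice spacing, ...)."""


class UndefinedMetricError(EllipstackError, ValueError):
    """An evaluation metric is undefined for the given inputs (empty masks...)."""


class ShellUndefinedError(EllipstackError, ValueError):
    """The outside shell used for gray-level estimation is empty."""


class MissingInputError(EllipstackError, ValueError):
    """A required input (e.g. the image volume for refinement) was not given."""


class StackFitError(EllipstackError, ValueError):
    """One or more slices of a stack could not be fitted; names the slices."""

    def __init__(self, failures):
        self.failures = list(failures)  # list of (slice_index, z, exception)
        msg = "; ".join(
            f"slice {i} (z={z:g} mm): {exc}" for i, z, exc in self.failures
        )
        super().__init__(f"ellipse fit failed for {len(self.failures)} slice(s): {msg}")
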