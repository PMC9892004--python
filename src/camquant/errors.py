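"""Exception hierarchy.

Everything raised on bad input or degenerate geometry derives from
:class:`CamquantError` so callers can catch one type at pipeline level.
"""


class CamquantError(ValueError):
    """Base class for all camquant-specific errors."""


class FormatError(CamquantError):
    """File content does not match the declared layout (e.g. channel count)."""


class SegmentationError(CamquantError):
    """A segmentation step produced no usable object."""


class ContourError(CamquantError):
    """Contour extraction failed (empty mask, multiple components, too small)."""


class NoContactError(CamquantError):
    """A doublet metric was requested but the two cells share no interface."""


class FitError(CamquantError):
    """A model fit is degenerate (collinear contour, all-zero areas, ...)."""


class GeometryError(CamquantError):
    """Fitted geometry is internally inconsistent."""


class ParameterError(CamquantError):
    """Synthetic-data parameters are outside their valid domain."""


class PackingError(CamquantError):
    """Sphere packing failed within the attempt budget."""
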