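"""Exception hierarchy for rootkin.

All rootkin-specific failures derive from :class:`RootkinError` so callers
can catch one base class at the CLI boundary.
"""


class RootkinError(Exception):
    """Base class for all rootkin errors."""


class InvalidPoseError(RootkinError):
    """Rotation matrix is not a proper orthonormal rotation."""


class DegenerateGeometryError(RootkinError):
    """Stereo geometry cannot resolve a 3D point (zero baseline, parallel rays)."""


class PointAtInfinityError(RootkinError):
    """Homogeneous triangulation solution has (near-)zero w component."""


class AlreadyCorrectedError(RootkinError):
    """Water depth correction applied to an already-corrected trajectory."""


class UnderdeterminedFitError(RootkinError):
    """Not enough depth spread in calibration corners to fit the water line."""


class GridMismatchError(RootkinError):
    """Two series that must share a time grid do not."""


class SchemaError(RootkinError):
    """Malformed tabular input (missing column, bad row, non-monotone time)."""


class OutOfViewError(RootkinError):
    """A simulated scene point falls outside a camera frustum."""


class NoPeakError(RootkinError):
    """Spectrum has no non-zero bin to define a main period."""
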