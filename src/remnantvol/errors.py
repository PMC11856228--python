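"""Exception hierarchy for remnantvol.

All package-specific failures derive from :class:`RemnantVolError` so callers
(and the CLI) can distinguish validation problems from programming errors.
"""


class RemnantVolError(Exception):
    """Base class for all remnantvol errors."""


class NonIntegerFactor(RemnantVolError):
    """SPECT/CT in-plane spacing ratio is not an integer within tolerance."""


class ShapeMismatch(RemnantVolError):
    """Resampled SPECT extent does not match the CT extent."""


class MissingGeometry(RemnantVolError):
    """A series-geometry record lacks origin or spacing information."""


class DegenerateHistogram(RemnantVolError):
    """All values identical; no threshold can split them into two classes."""


class InvalidRange(RemnantVolError):
    """A slice range with z_first > z_last."""


class OutOfBounds(RemnantVolError):
    """ROI polygon or slice range falls outside the image grid."""


class EmptyRoi(RemnantVolError):
    """ROI rasterization produced no voxels."""


class EmptyMask(RemnantVolError):
    """An operation requiring a non-empty voxel mask received an empty one."""


class ZeroDenominator(RemnantVolError):
    """A metric denominator (actual or calculated volume) is zero."""


class GeometryError(RemnantVolError):
    """Phantom spheres overlap each other or exit the neck cylinder / grid."""


class MixedSeries(RemnantVolError):
    """A DICOM directory contains more than one series."""


class NonUniformSpacing(RemnantVolError):
    """DICOM slice positions are not uniformly spaced within tolerance."""


class UnsupportedFormat(RemnantVolError):
    """Input path is not a DICOM directory, NIfTI file, or NPZ archive."""
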