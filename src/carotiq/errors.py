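"""Exception hierarchy used across the package."""


class CarotiqError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(CarotiqError):
    """Image or array has the wrong number of dimensions."""


class OrientationError(CarotiqError):
    """NIfTI affine is not an axis-aligned orthogonal matrix."""


class EmptyOverlapError(CarotiqError):
    """Source and target grids do not overlap in world space."""


class GridMismatchError(CarotiqError):
    """Two objects expected on the same voxel grid are not."""


class ModalityError(CarotiqError):
    """Volume has the wrong modality for the requested operation."""


class GeometryError(CarotiqError):
    """Invalid geometric configuration (network extents, tube placement)."""


class EmptyMaskError(CarotiqError):
    """Operation requires a nonempty mask."""


class SampleSizeError(CarotiqError):
    """Too few paired observations for the requested statistic."""
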