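"""Volume/grid/mask data model, NIfTI I/O and resampling.

Conventions
-----------
Arrays are indexed ``(z, y, x)`` — slice, row, column — with per-axis voxel
spacing in mm.  The default analysis grid uses spacing ``(3.0, 1.37, 1.37)``
mm, i.e. 3 mm in the slice (scanner axial) direction.  World coordinates are
RAS-aligned: the array ``x`` axis increases toward the patient's left side
(the mask label ``carotid_left`` therefore lives on the +x half of the
volume), ``y`` toward posterior rows, ``z`` toward the head.  Only
axis-aligned orthogonal affines are supported; oblique acquisitions are out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    DimensionError,
    EmptyOverlapError,
    GridMismatchError,
    OrientationError,
)

CT_HU = "CT_HU"
PET_SUV = "PET_SUV"
MODALITIES = (CT_HU, PET_SUV)

#: out-of-field fill value per modality
BACKGROUND_FILL = {CT_HU: -1000.0, PET_SUV: 0.0}

MASK_LABELS = ("carotid_left", "carotid_right", "bone", "other")

#: label-map class codes
BACKGROUND, CAROTID_LEFT, CAROTID_RIGHT = 0, 1, 2


@dataclass(frozen=True)
class VoxelGrid:
    """Regular axis-aligned voxel lattice in world (mm) coordinates.

    ``origin_mm`` is the world position of the *center* of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or len(self.spacing_mm) != 3 or len(self.origin_mm) != 3:
            raise DimensionError("grid must be three-dimensional")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))
        if any(s < 1 for s in self.shape):
            raise DimensionError(f"shape components must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacings must be positive, got {self.spacing_mm}")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    def axis_centers_mm(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one array axis."""
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(self.shape[axis])

    def world_extent_mm(self, axis: int) -> tuple[float, float]:
        """Closed interval spanned by voxel centers along an axis."""
        c = self.axis_centers_mm(axis)
        return float(c[0]), float(c[-1])


def _check_values(values: np.ndarray, modality: str) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim != 3:
        raise DimensionError(f"expected a 3-D array, got ndim={values.ndim}")
    if not np.all(np.isfinite(values)):
        raise ValueError("volume contains non-finite values")
    if modality == CT_HU and (values.min() < -1100 or values.max() > 4000):
        raise ValueError("CT values outside the plausible [-1100, 4000] HU range")
    if modality == PET_SUV and values.min() < 0:
        raise ValueError("PET SUV values must be nonnegative")
    return values


@dataclass
class ScalarVolume:
    """A 3-D scalar field (HU or SUV) on an explicit voxel grid."""

    grid: VoxelGrid
    values: np.ndarray
    modality: str

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.values = _check_values(self.values, self.modality)
        if tuple(self.values.shape) != self.grid.shape:
            raise GridMismatchError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )


@dataclass
class BinaryMask:
    """A volume of interest on a grid, with an anatomical label."""

    grid: VoxelGrid
    voxels: np.ndarray
    label: str = "other"

    def __post_init__(self):
        if self.label not in MASK_LABELS:
            raise ValueError(f"unknown mask label {self.label!r}")
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise DimensionError(f"mask must be 3-D, got ndim={self.voxels.ndim}")
        if tuple(self.voxels.shape) != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class LabelMap:
    """Per-voxel class map: 0 background, 1 carotid left, 2 carotid right."""

    grid: VoxelGrid
    classes: np.ndarray

    def __post_init__(self):
        self.classes = np.asarray(self.classes).astype(np.uint8)
        if self.classes.ndim != 3:
            raise DimensionError("label map must be 3-D")
        if tuple(self.classes.shape) != self.grid.shape:
            raise GridMismatchError("label map shape does not match its grid")
        extra = set(np.unique(self.classes)) - {BACKGROUND, CAROTID_LEFT, CAROTID_RIGHT}
        if extra:
            raise ValueError(f"undeclared class codes {sorted(extra)}")

    def side_mask(self, label: str) -> BinaryMask:
        code = {"carotid_left": CAROTID_LEFT, "carotid_right": CAROTID_RIGHT}[label]
        return BinaryMask(self.grid, self.classes == code, label=label)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _grid_to_affine(grid: VoxelGrid) -> np.ndarray:
    # array axes (z, y, x) are written as NIfTI (i, j, k) = (x, y, z)
    sz, sy, sx = grid.spacing_mm
    oz, oy, ox = grid.origin_mm
    aff = np.diag([sx, sy, sz, 1.0])
    aff[:3, 3] = [ox, oy, oz]
    return aff


def _affine_to_grid(aff: np.ndarray, shape_xyz: tuple[int, ...]) -> VoxelGrid:
    rot = aff[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-4):
        raise OrientationError("only axis-aligned orthogonal affines are supported")
    sx, sy, sz = np.diag(rot)
    if sx <= 0 or sy <= 0 or sz <= 0:
        raise OrientationError("affine not canonicalized to RAS")
    ox, oy, oz = aff[:3, 3]
    nx, ny, nz = shape_xyz
    return VoxelGrid((nz, ny, nx), (float(sz), float(sy), float(sx)), (float(oz), float(oy), float(ox)))


def read_volume(path, modality: str) -> ScalarVolume:
    """Read a 3-D NIfTI image into a :class:`ScalarVolume`.

    The image is reoriented to the closest RAS orientation; the grid spacing
    and origin come from the affine.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise DimensionError(f"expected a 3-D image, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    grid = _affine_to_grid(img.affine, img.shape)
    data = np.asarray(img.dataobj)  # (x, y, z)
    values = np.ascontiguousarray(data.transpose(2, 1, 0))
    return ScalarVolume(grid, values, modality)


def read_mask(path, label: str = "other") -> BinaryMask:
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise DimensionError(f"expected a 3-D image, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    grid = _affine_to_grid(img.affine, img.shape)
    data = np.asarray(img.dataobj).transpose(2, 1, 0)
    return BinaryMask(grid, data > 0, label=label)


def read_labelmap(path) -> LabelMap:
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise DimensionError(f"expected a 3-D image, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    grid = _affine_to_grid(img.affine, img.shape)
    data = np.rint(np.asarray(img.dataobj)).astype(np.uint8).transpose(2, 1, 0)
    return LabelMap(grid, data)


def write_volume(vol, path) -> None:
    """Write a ScalarVolume, BinaryMask or LabelMap as NIfTI.

    Masks and label maps are stored as 8-bit integers; scalar volumes keep
    their floating dtype so a read-back is bitwise identical.
    """
    path = Path(path)
    if isinstance(vol, BinaryMask):
        data = vol.voxels.astype(np.uint8)
        grid = vol.grid
    elif isinstance(vol, LabelMap):
        data = vol.classes.astype(np.uint8)
        grid = vol.grid
    elif isinstance(vol, ScalarVolume):
        data = vol.values
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        grid = vol.grid
    else:
        raise TypeError(f"cannot write object of type {type(vol).__name__}")
    img = nib.Nifti1Image(np.ascontiguousarray(data.transpose(2, 1, 0)), _grid_to_affine(grid))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling


def _target_coords_in_source(src: VoxelGrid, dst: VoxelGrid):
    """Fractional source indices of every target voxel center, per axis."""
    axes = []
    for ax in range(3):
        world = dst.axis_centers_mm(ax)
        axes.append((world - src.origin_mm[ax]) / src.spacing_mm[ax])
    return axes


def _check_overlap(src: VoxelGrid, dst: VoxelGrid) -> None:
    for ax in range(3):
        slo, shi = src.world_extent_mm(ax)
        dlo, dhi = dst.world_extent_mm(ax)
        # allow half-voxel slack: centers just outside still draw on the field
        pad = 0.5 * src.spacing_mm[ax]
        if dhi < slo - pad or dlo > shi + pad:
            raise EmptyOverlapError(
                f"grids disjoint along axis {ax}: source centers span "
                f"[{slo}, {shi}] mm, target [{dlo}, {dhi}] mm"
            )


def resample_to_grid(vol: ScalarVolume, target: VoxelGrid, mode: str = "trilinear") -> ScalarVolume:
    """Resample a volume onto ``target`` by sampling at voxel centers.

    Out-of-field voxels are filled with the modality background
    (−1000 HU for CT, 0 for PET).
    """
    if mode not in ("nearest", "trilinear"):
        raise ValueError(f"unknown mode {mode!r}")
    src = vol.grid
    if target == src:
        return ScalarVolume(target, vol.values.copy(), vol.modality)
    _check_overlap(src, target)
    fill = BACKGROUND_FILL[vol.modality]
    fz, fy, fx = _target_coords_in_source(src, target)
    if mode == "nearest":
        out = np.full(target.shape, fill, dtype=vol.values.dtype)
        iz = np.floor(fz + 0.5).astype(np.int64)
        iy = np.floor(fy + 0.5).astype(np.int64)
        ix = np.floor(fx + 0.5).astype(np.int64)
        okz = (iz >= 0) & (iz < src.shape[0])
        oky = (iy >= 0) & (iy < src.shape[1])
        okx = (ix >= 0) & (ix < src.shape[2])
        inside = okz[:, None, None] & oky[None, :, None] & okx[None, None, :]
        gz, gy, gx = np.meshgrid(np.clip(iz, 0, src.shape[0] - 1),
                                 np.clip(iy, 0, src.shape[1] - 1),
                                 np.clip(ix, 0, src.shape[2] - 1), indexing="ij")
        out[:] = vol.values[gz, gy, gx]
        out[~inside] = fill
    else:
        gz, gy, gx = np.meshgrid(fz, fy, fx, indexing="ij")
        out = ndimage.map_coordinates(
            vol.values.astype(np.float64), np.stack([gz, gy, gx]),
            order=1, mode="constant", cval=fill,
        )
    return ScalarVolume(target, out, vol.modality)


def resample_mask_to_grid(mask: BinaryMask, target: VoxelGrid) -> BinaryMask:
    """Nearest-neighbour resampling of a binary mask."""
    as_vol = ScalarVolume(mask.grid, mask.voxels.astype(np.float32), PET_SUV)
    res = resample_to_grid(as_vol, target, mode="nearest")
    return BinaryMask(target, res.values > 0.5, label=mask.label)
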