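"""Synthetic neck phantoms: paired CT/PET volumes with ground-truth masks.

Each phantom emulates the statistical structure the segmentation pipeline
assumes in a noncontrast-CT + NaF-PET neck study:

* two roughly vertical tubular common carotids (sinusoidally perturbed
  centerlines) with CT density barely above soft tissue and PET uptake
  around SUV 1;
* a posterior-midline vertebra-like bone column, bright on CT, with high
  NaF uptake whose point-spread halo spills toward the carotids;
* optionally, jugular-vein-like distractor tubes: vessel-like CT density
  but background-level SUV;
* additive Gaussian noise per modality.

The bone's excess activity is blurred with a Gaussian point-spread function
before noise is added, so the spill-over halo exists on the noiseless map;
the carotid and background activity are left unblurred so the carotid
tissue SUV is exactly the per-case draw.

All randomness flows from one integer seed; identical (spec, seed) produce
bitwise-identical volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import EmptyMaskError, GeometryError
from .imagevol import (
    CT_HU,
    PET_SUV,
    BinaryMask,
    ScalarVolume,
    VoxelGrid,
    read_mask,
    read_volume,
    write_volume,
)

DEFAULT_GRID = VoxelGrid(shape=(60, 128, 128), spacing_mm=(3.0, 1.37, 1.37))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic CT/PET neck cohort generator.

    SUV parameters follow the cohort-level summary of a healthy/angina NaF
    study population (carotid SUVmean near 1); HU values are nominal
    noncontrast-CT tissue densities.
    """

    grid: VoxelGrid = DEFAULT_GRID
    carotid_radius_mm: float = 3.0
    carotid_curvature_amplitude_mm: float = 3.0
    carotid_suv_mean: float = 1.0
    carotid_suv_sd: float = 0.15
    background_suv: float = 0.5
    bone_suv: float = 5.0
    bone_hu: float = 700.0
    soft_tissue_hu: float = 40.0
    vessel_hu: float = 45.0
    psf_fwhm_mm: float = 6.0
    noise_sd_suv: float = 0.1
    ct_noise_sd_hu: float = 10.0
    include_jugular_distractor: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.carotid_radius_mm < 0 or self.carotid_suv_sd < 0:
            raise ValueError("radii and SDs must be nonnegative")
        if self.carotid_curvature_amplitude_mm < 0:
            raise ValueError("curvature amplitude must be nonnegative")
        if min(self.carotid_suv_mean, self.background_suv, self.bone_suv) < 0:
            raise ValueError("SUV parameters must be nonnegative")
        if self.noise_sd_suv < 0 or self.ct_noise_sd_hu < 0:
            raise ValueError("noise SDs must be nonnegative")


@dataclass
class PhantomCase:
    """One synthetic subject: CT, PET and ground-truth masks on one grid."""

    ct: ScalarVolume
    pet: ScalarVolume
    truth_left: BinaryMask
    truth_right: BinaryMask
    truth_bone: BinaryMask
    case_id: str = "case"


# ---------------------------------------------------------------------------
# geometry helpers


def _centerline(grid: VoxelGrid, x0: float, y0: float, amplitude: float,
                phase_x: float, phase_y: float, step_mm: float = 0.25) -> np.ndarray:
    """Polyline points (z, y, x) of a sinusoidally perturbed vertical tube."""
    z_lo, z_hi = grid.world_extent_mm(0)
    z_lo -= grid.spacing_mm[0]
    z_hi += grid.spacing_mm[0]
    z = np.arange(z_lo, z_hi + step_mm, step_mm)
    span = max(z_hi - z_lo, 1e-9)
    x = x0 + amplitude * np.sin(2 * np.pi * (z - z_lo) / span + phase_x)
    y = y0 + amplitude * np.sin(2 * np.pi * (z - z_lo) / span + phase_y)
    return np.column_stack([z, y, x])


def _rasterize_tube(grid: VoxelGrid, polyline: np.ndarray, radius_mm: float) -> np.ndarray:
    """Voxels whose center lies within ``radius_mm`` of the centerline."""
    for ax, name in ((1, "y"), (2, "x")):
        lo, hi = grid.world_extent_mm(ax)
        if polyline[:, ax].min() - radius_mm < lo or polyline[:, ax].max() + radius_mm > hi:
            raise GeometryError(f"carotid tube exits the grid along {name}")
    zc = grid.axis_centers_mm(0)
    yc = grid.axis_centers_mm(1)
    xc = grid.axis_centers_mm(2)
    # restrict the distance query to the tube's bounding box
    ysel = np.flatnonzero((yc >= polyline[:, 1].min() - radius_mm - 1) &
                          (yc <= polyline[:, 1].max() + radius_mm + 1))
    xsel = np.flatnonzero((xc >= polyline[:, 2].min() - radius_mm - 1) &
                          (xc <= polyline[:, 2].max() + radius_mm + 1))
    pts = np.stack(np.meshgrid(zc, yc[ysel], xc[xsel], indexing="ij"), axis=-1).reshape(-1, 3)
    dist, _ = cKDTree(polyline).query(pts, workers=1)
    sub = (dist <= radius_mm).reshape(len(zc), len(ysel), len(xsel))
    mask = np.zeros(grid.shape, dtype=bool)
    mask[np.ix_(np.arange(len(zc)), ysel, xsel)] = sub
    return mask


def _cylinder(grid: VoxelGrid, y0: float, x0: float, radius_mm: float) -> np.ndarray:
    yc = grid.axis_centers_mm(1)
    xc = grid.axis_centers_mm(2)
    d2 = (yc[:, None] - y0) ** 2 + (xc[None, :] - x0) ** 2
    return np.broadcast_to(d2 <= radius_mm ** 2, grid.shape).copy()


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One draw from N(mean, sd) truncated to mean ± 3 sd."""
    if sd == 0:
        return mean
    for _ in range(100):
        v = rng.normal(mean, sd)
        if abs(v - mean) <= 3 * sd:
            return float(v)
    return mean


# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one paired CT/PET phantom with ground-truth masks."""
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    ylo, yhi = grid.world_extent_mm(1)
    xlo, xhi = grid.world_extent_mm(2)
    y_mid, x_mid = (ylo + yhi) / 2, (xlo + xhi) / 2
    fov_y, fov_x = yhi - ylo, xhi - xlo

    # anatomy layout (world mm): +x is the patient-left side, +y posterior
    lateral = 0.14 * fov_x                       # carotid offset from midline
    y_carotid = y_mid + 0.03 * fov_y             # slightly posterior
    y_bone = y_mid + 0.20 * fov_y                # vertebral column, posterior
    bone_radius = 0.07 * fov_y                   # ~12 mm on the default grid
    jug_lateral = lateral + 9.0
    jug_y = y_carotid - 7.0
    jug_radius = 4.5

    phases = rng.uniform(0, 2 * np.pi, size=4)
    left_line = _centerline(grid, x_mid + lateral, y_carotid,
                            spec.carotid_curvature_amplitude_mm, phases[0], phases[1])
    right_line = _centerline(grid, x_mid - lateral, y_carotid,
                             spec.carotid_curvature_amplitude_mm, phases[2], phases[3])
    left = _rasterize_tube(grid, left_line, spec.carotid_radius_mm)
    right = _rasterize_tube(grid, right_line, spec.carotid_radius_mm)
    bone = _cylinder(grid, y_bone, x_mid, bone_radius)
    bone &= ~(left | right)

    body = ((grid.axis_centers_mm(1)[:, None] - y_mid) ** 2 / (0.47 * fov_y) ** 2 +
            (grid.axis_centers_mm(2)[None, :] - x_mid) ** 2 / (0.47 * fov_x) ** 2) <= 1.0
    body = np.broadcast_to(body, grid.shape)

    ct = np.full(grid.shape, -1000.0)
    ct[body] = spec.soft_tissue_hu
    ct[bone] = spec.bone_hu
    ct[left | right] = spec.vessel_hu

    pet = np.zeros(grid.shape)
    pet[body] = spec.background_suv
    suv_left = _truncated_normal(rng, spec.carotid_suv_mean, spec.carotid_suv_sd)
    suv_right = _truncated_normal(rng, spec.carotid_suv_mean, spec.carotid_suv_sd)
    pet[left] = suv_left
    pet[right] = suv_right

    if spec.include_jugular_distractor:
        for sign in (+1, -1):
            jug = _cylinder(grid, jug_y, x_mid + sign * jug_lateral, jug_radius)
            jug &= ~(left | right | bone)
            ct[jug] = spec.vessel_hu
        # jugular SUV stays at background level (no NaF avidity)

    # bone excess activity, blurred by the scanner point spread -> halo
    excess = np.zeros(grid.shape)
    excess[bone] = spec.bone_suv - spec.background_suv
    if spec.psf_fwhm_mm > 0:
        sigma_vox = [spec.psf_fwhm_mm / 2.3548200450309493 / s for s in grid.spacing_mm]
        excess = ndimage.gaussian_filter(excess, sigma=sigma_vox)
    pet = pet + excess

    if spec.ct_noise_sd_hu > 0:
        ct = ct + rng.normal(0.0, spec.ct_noise_sd_hu, size=grid.shape)
    if spec.noise_sd_suv > 0:
        pet = pet + rng.normal(0.0, spec.noise_sd_suv, size=grid.shape)
    ct = np.clip(ct, -1100.0, 4000.0)
    pet = np.clip(pet, 0.0, None)

    return PhantomCase(
        ct=ScalarVolume(grid, ct, CT_HU),
        pet=ScalarVolume(grid, pet, PET_SUV),
        truth_left=BinaryMask(grid, left, "carotid_left"),
        truth_right=BinaryMask(grid, right, "carotid_right"),
        truth_bone=BinaryMask(grid, bone, "bone"),
        case_id=f"phantom-{spec.seed}",
    )


#: per-case jitter ranges used by generate_cohort
RADIUS_JITTER_MM = (2.5, 4.0)
CURVATURE_JITTER_MM = (1.0, 5.0)


def generate_cohort(n: int, spec: PhantomSpec, seed: int) -> list[PhantomCase]:
    """Generate ``n`` phantoms with per-case jittered tube geometry."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        radius = rng.uniform(*RADIUS_JITTER_MM)
        curvature = rng.uniform(*CURVATURE_JITTER_MM)
        case_seed = int(rng.integers(0, 2**31 - 1))
        case_spec = replace(spec, carotid_radius_mm=float(radius),
                            carotid_curvature_amplitude_mm=float(curvature),
                            seed=case_seed)
        case = generate_phantom(case_spec)
        case.case_id = f"case-{i:03d}"
        cases.append(case)
    return cases


def _radius_footprint(grid: VoxelGrid, radius_mm: float) -> np.ndarray:
    """Structuring element: offsets whose world distance is <= radius."""
    half = [int(np.floor(radius_mm / s + 1e-9)) for s in grid.spacing_mm]
    zz, yy, xx = np.meshgrid(*(np.arange(-h, h + 1) for h in half), indexing="ij")
    d = np.sqrt((zz * grid.spacing_mm[0]) ** 2 +
                (yy * grid.spacing_mm[1]) ** 2 +
                (xx * grid.spacing_mm[2]) ** 2)
    return d <= radius_mm + 1e-9


def perturb_mask(mask: BinaryMask, dilation_mm: float, erosion_mm: float,
                 seed: int, flip_rate: float = 0.05) -> BinaryMask:
    """Simulate a second observer's segmentation of the same structure.

    Morphological dilation then erosion (world-metric structuring elements),
    followed by random flips of boundary voxels at ``flip_rate``.
    """
    if dilation_mm < 0 or erosion_mm < 0:
        raise ValueError("dilation/erosion radii must be nonnegative")
    if mask.count == 0:
        raise EmptyMaskError("cannot perturb an empty mask")
    out = mask.voxels.copy()
    if dilation_mm > 0:
        out = ndimage.binary_dilation(out, structure=_radius_footprint(mask.grid, dilation_mm))
    if erosion_mm > 0:
        out = ndimage.binary_erosion(out, structure=_radius_footprint(mask.grid, erosion_mm))
    if flip_rate > 0:
        rng = np.random.default_rng(seed)
        conn = ndimage.generate_binary_structure(3, 1)
        inner = out & ~ndimage.binary_erosion(out, structure=conn)
        outer = ndimage.binary_dilation(out, structure=conn) & ~out
        boundary = inner | outer
        flips = boundary & (rng.random(out.shape) < flip_rate)
        out = out ^ flips
    return BinaryMask(mask.grid, out, label=mask.label)


# ---------------------------------------------------------------------------
# cohort I/O: directory of NIfTI files + JSON manifest


def write_cohort(cases: list[PhantomCase], out_dir, spec: PhantomSpec | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"cases": [], "spec": _spec_to_json(spec) if spec is not None else None}
    for case in cases:
        entry = {"case_id": case.case_id}
        for name, obj in (("ct", case.ct), ("pet", case.pet),
                          ("truth_left", case.truth_left),
                          ("truth_right", case.truth_right),
                          ("truth_bone", case.truth_bone)):
            fname = f"{case.case_id}_{name}.nii.gz"
            write_volume(obj, out_dir / fname)
            entry[name] = fname
        manifest["cases"].append(entry)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir / "manifest.json"


def read_cohort(manifest_path) -> list[PhantomCase]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    cases = []
    for entry in manifest["cases"]:
        cases.append(PhantomCase(
            ct=read_volume(base / entry["ct"], CT_HU),
            pet=read_volume(base / entry["pet"], PET_SUV),
            truth_left=read_mask(base / entry["truth_left"], "carotid_left"),
            truth_right=read_mask(base / entry["truth_right"], "carotid_right"),
            truth_bone=read_mask(base / entry["truth_bone"], "bone"),
            case_id=entry["case_id"],
        ))
    return cases


def _spec_to_json(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["grid"] = {"shape": spec.grid.shape, "spacing_mm": spec.grid.spacing_mm,
                 "origin_mm": spec.grid.origin_mm}
    return d
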