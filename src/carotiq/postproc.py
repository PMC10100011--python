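"""Postprocessing of raw carotid segmentations.

Two operators clean up the initial per-voxel classification:

1. *Largest almost-connected component.* Standard 26-connected components
   are grouped by the transitive closure of "minimum voxel-center distance
   ≤ gap_mm" (default 20 mm), so a carotid fragmented by a few missing
   slices still counts as one object; the largest group (total voxel count)
   is kept.

2. *SUV leakage removal.* Very hot voxels inside the VOI (SUV more than
   ``leak_sd_multiplier`` SDs above the VOI mean) whose nearest PET
   activation maximum lies inside the bone mask are attributed to bone
   spill-over and removed.  Statistics use the mask before any removal
   (population SD), applied in a single pass.

The bone mask itself comes from a CT threshold stand-in
(:func:`bone_mask_from_ct`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ModalityError
from .imagevol import CT_HU, PET_SUV, BinaryMask, ScalarVolume

#: 26-neighbourhood structuring element
STRUCT_26 = ndimage.generate_binary_structure(3, 3)


@dataclass(frozen=True)
class PostprocParams:
    gap_mm: float = 20.0
    leak_sd_multiplier: float = 2.0
    bone_hu_threshold: float = 200.0
    maxima_min_separation_mm: float = 5.0
    min_bone_component_ml: float = 0.5

    def __post_init__(self):
        if self.gap_mm < 0:
            raise ValueError("gap_mm must be nonnegative")
        if self.leak_sd_multiplier < 0:
            raise ValueError("leak_sd_multiplier must be nonnegative")


def bone_mask_from_ct(ct: ScalarVolume, params: PostprocParams = PostprocParams()) -> BinaryMask:
    """Threshold stand-in for a dedicated bone segmentation tool.

    HU >= threshold, then 1-voxel morphological closing and removal of
    components smaller than ``min_bone_component_ml``.
    """
    if ct.modality != CT_HU:
        raise ModalityError(f"bone segmentation expects a CT volume, got {ct.modality}")
    raw = ct.values >= params.bone_hu_threshold
    closed = ndimage.binary_closing(raw, structure=ndimage.generate_binary_structure(3, 1))
    labels, n = ndimage.label(closed, structure=STRUCT_26)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes * ct.grid.voxel_volume_ml >= params.min_bone_component_ml) + 1
        closed = np.isin(labels, keep)
    return BinaryMask(ct.grid, closed, label="bone")


def _component_coords_mm(mask: BinaryMask):
    """26-connected components as world-coordinate arrays, plus voxel indices."""
    labels, n = ndimage.label(mask.voxels, structure=STRUCT_26)
    spacing = np.asarray(mask.grid.spacing_mm)
    origin = np.asarray(mask.grid.origin_mm)
    comps = []
    for i in range(1, n + 1):
        idx = np.argwhere(labels == i)
        comps.append((idx, idx * spacing + origin))
    return labels, comps


def almost_connected_filter(mask: BinaryMask, params: PostprocParams = PostprocParams()) -> BinaryMask:
    """Keep the largest almost-connected component of a mask.

    Components whose minimum voxel-center-to-voxel-center distance is at
    most ``gap_mm`` belong to the same group (transitively); the group with
    the largest total voxel count is returned.  Ties go to the group
    containing the lexicographically smallest voxel.  An empty mask is
    returned unchanged.
    """
    if mask.count == 0:
        return BinaryMask(mask.grid, mask.voxels.copy(), label=mask.label)
    labels, comps = _component_coords_mm(mask)
    n = len(comps)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    trees = [cKDTree(c[1]) for c in comps]
    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            # minimum inter-component distance via KD-tree nearest queries
            d = trees[i].query(comps[j][1], k=1, workers=1,
                               distance_upper_bound=params.gap_mm + 1e-9)[0]
            if np.min(d) <= params.gap_mm + 1e-9:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    sizes = {r: sum(len(comps[i][0]) for i in members) for r, members in groups.items()}
    max_size = max(sizes.values())
    best, best_key = None, None
    for r, members in groups.items():
        if sizes[r] != max_size:
            continue
        first_voxel = min(tuple(v) for i in members for v in comps[i][0])
        if best_key is None or first_voxel < best_key:
            best, best_key = members, first_voxel
    keep = np.isin(labels, [i + 1 for i in best])
    return BinaryMask(mask.grid, keep, label=mask.label)


def local_suv_maxima(pet: ScalarVolume, params: PostprocParams = PostprocParams()) -> list[tuple[int, int, int]]:
    """PET activation maxima: 26-neighbourhood local maxima with plateau
    handling and minimum-separation suppression.

    A plateau (connected set of equal values dominating its outer boundary)
    is represented by its lexicographically smallest voxel.  Among maxima
    closer than ``maxima_min_separation_mm`` only the highest-SUV one is
    kept (ties to the lexicographically smallest index).  A constant volume
    has no maxima.
    """
    if pet.modality != PET_SUV:
        raise ModalityError(f"expected a PET volume, got {pet.modality}")
    x = pet.values
    footprint = STRUCT_26.copy()
    footprint[1, 1, 1] = False
    neigh_max = ndimage.maximum_filter(x, footprint=footprint, mode="constant", cval=-np.inf)
    cand = x >= neigh_max  # equal neighbours are plateau members, never larger
    # adjacent candidates always share a value, so plain labeling gives plateaus
    labels, n = ndimage.label(cand, structure=STRUCT_26)
    if n == 0:
        return []
    # a plateau must strictly dominate its outer boundary: drop any plateau
    # with an equal-valued neighbour outside itself (that neighbour failed
    # candidacy, so somewhere the plateau's level is not a summit)
    bad = np.zeros(n + 1, dtype=bool)
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                src = tuple(slice(max(d, 0), s + min(d, 0))
                            for d, s in zip((dz, dy, dx), x.shape))
                dst = tuple(slice(max(-d, 0), s + min(-d, 0))
                            for d, s in zip((dz, dy, dx), x.shape))
                leak = (cand[src] & (x[src] == x[dst])
                        & (labels[src] != labels[dst]))
                if leak.any():
                    bad[np.unique(labels[src][leak])] = True
    labels[bad[labels]] = 0
    flat = labels.ravel()
    nz = np.flatnonzero(flat)
    if len(nz) == 0 or len(nz) == x.size:  # constant volume: nothing to dominate
        return []
    # C-order scan is lexicographic, so the first occurrence of each label
    # is its lexicographically smallest voxel
    _, first = np.unique(flat[nz], return_index=True)
    peak_flat = nz[first]
    peak_idx = np.column_stack(np.unravel_index(peak_flat, x.shape))
    peak_val = x.ravel()[peak_flat]

    # minimum-separation suppression, strongest first (ties lexicographic)
    spacing = np.asarray(pet.grid.spacing_mm)
    pos_mm = peak_idx * spacing
    order = np.lexsort((peak_idx[:, 2], peak_idx[:, 1], peak_idx[:, 0], -peak_val))
    tree = cKDTree(pos_mm)
    alive = np.ones(len(peak_idx), dtype=bool)
    kept: list[tuple[int, int, int]] = []
    for i in order:
        if not alive[i]:
            continue
        kept.append(tuple(int(v) for v in peak_idx[i]))
        near = tree.query_ball_point(pos_mm[i],
                                     params.maxima_min_separation_mm - 1e-9,
                                     workers=1)
        for j in near:
            alive[j] = False
    return kept


def remove_suv_leakage(mask: BinaryMask, pet: ScalarVolume, bone: BinaryMask,
                       params: PostprocParams = PostprocParams()) -> BinaryMask:
    """Remove bone spill-over from a carotid VOI.

    Mask voxels with SUV above mean + ``leak_sd_multiplier``·SD (statistics
    over the input mask, population SD) whose nearest activation maximum
    (world distance; ties to higher SUV, then lexicographic order) lies in
    the bone mask are dropped.  Never adds voxels.  With an empty bone mask
    the input is returned unchanged.
    """
    if mask.grid != pet.grid or mask.grid != bone.grid:
        raise ValueError("mask, PET and bone mask must share one grid")
    if mask.count == 0 or bone.count == 0:
        return BinaryMask(mask.grid, mask.voxels.copy(), label=mask.label)
    vals = pet.values[mask.voxels]
    mu, sigma = float(np.mean(vals)), float(np.std(vals))  # population SD
    threshold = mu + params.leak_sd_multiplier * sigma
    cand_map = mask.voxels & (pet.values > threshold)
    cand = np.argwhere(cand_map)
    if len(cand) == 0:
        return BinaryMask(mask.grid, mask.voxels.copy(), label=mask.label)
    maxima = local_suv_maxima(pet, params)
    if not maxima:
        return BinaryMask(mask.grid, mask.voxels.copy(), label=mask.label)
    spacing = np.asarray(mask.grid.spacing_mm)
    max_arr = np.asarray(maxima)
    max_mm = max_arr * spacing
    max_suv = pet.values[tuple(max_arr.T)]
    # maxima come lexicographically pre-sorted within equal (distance, -SUV)
    # keys after the stable lexsort below
    out = mask.voxels.copy()
    for voxel in cand:
        d = np.linalg.norm(max_mm - voxel * spacing, axis=1)
        # nearest; ties to higher SUV, then lexicographically smallest index
        keys = np.lexsort((max_arr[:, 2], max_arr[:, 1], max_arr[:, 0],
                           -max_suv, np.round(d, 9)))
        chosen = maxima[keys[0]]
        if bone.voxels[chosen]:
            out[tuple(voxel)] = False
    return BinaryMask(mask.grid, out, label=mask.label)
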