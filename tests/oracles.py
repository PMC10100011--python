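"""Brute-force reference implementations used by the test suite only."""

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from carotiq.imagevol import BinaryMask


def brute_force_largest_group(mask: BinaryMask, gap_mm: float) -> np.ndarray:
    """All-pairs inter-voxel distance matrix + union-find over components."""
    labels, n = ndimage.label(mask.voxels,
                              structure=ndimage.generate_binary_structure(3, 3))
    if n == 0:
        return np.zeros(mask.grid.shape, bool)
    spacing = np.asarray(mask.grid.spacing_mm)
    coords = [np.argwhere(labels == i + 1) * spacing for i in range(n)]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if cdist(coords[i], coords[j]).min() <= gap_mm + 1e-9:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    sizes = {r: sum((labels == i + 1).sum() for i in m) for r, m in groups.items()}
    best = max(groups, key=lambda r: sizes[r])
    return np.isin(labels, [i + 1 for i in groups[best]])


def brute_force_leakage_removal(mask, pet, bone, params):
    """Direct all-maxima scan for every above-threshold mask voxel."""
    from carotiq.postproc import local_suv_maxima

    vox = mask.voxels
    vals = pet.values[vox]
    thr = vals.mean() + params.leak_sd_multiplier * vals.std()
    maxima = local_suv_maxima(pet, params)
    expected = vox.copy()
    if not maxima or not bone.voxels.any():
        return expected
    spacing = np.asarray(mask.grid.spacing_mm)
    for vx in np.argwhere(vox & (pet.values > thr)):
        d = [np.linalg.norm((np.asarray(m) - vx) * spacing) for m in maxima]
        best = min(range(len(maxima)),
                   key=lambda i: (round(d[i], 9), -pet.values[maxima[i]], maxima[i]))
        if bone.voxels[maxima[best]]:
            expected[tuple(vx)] = False
    return expected
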