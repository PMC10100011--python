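"""VOI uptake quantification: volume and SUV statistics.

For a volume of interest V on a grid with voxel volume v (ml):

* ``vol_ml``   = |V| * v
* ``suv_mean`` = mean SUV over voxels of V (g/ml)
* ``suv_max``  = max SUV over voxels of V (g/ml)
* ``suv_total`` = suv_mean * vol_ml (g/ml * ml)

An empty VOI yields all-zero statistics with ``empty=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError, ModalityError
from .imagevol import PET_SUV, BinaryMask, ScalarVolume


@dataclass(frozen=True)
class UptakeStats:
    vol_ml: float
    suv_mean: float
    suv_max: float
    suv_total: float
    empty: bool = False

    def as_dict(self) -> dict:
        return {"vol_ml": self.vol_ml, "suv_mean": self.suv_mean,
                "suv_max": self.suv_max, "suv_total": self.suv_total}


def voi_volume_ml(mask: BinaryMask) -> float:
    """Segmented VOI volume in ml: foreground count times voxel volume."""
    return mask.count * mask.grid.voxel_volume_ml


def suv_stats(pet: ScalarVolume, mask: BinaryMask) -> UptakeStats:
    """SUV statistics of a PET volume inside a VOI."""
    if pet.modality != PET_SUV:
        raise ModalityError(f"expected PET_SUV volume, got {pet.modality}")
    if pet.grid != mask.grid:
        raise GridMismatchError("PET volume and mask are on different grids")
    if mask.count == 0:
        return UptakeStats(0.0, 0.0, 0.0, 0.0, empty=True)
    vals = pet.values[mask.voxels]
    vol = voi_volume_ml(mask)
    mx = float(np.max(vals))
    # summation order can push the mean of a constant VOI 1 ulp above the max
    mean = min(float(np.mean(vals)), mx)
    return UptakeStats(
        vol_ml=vol,
        suv_mean=mean,
        suv_max=mx,
        suv_total=mean * vol,
    )
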