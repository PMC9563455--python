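"""Numeric diagnostics of the image and mask feeding an extraction.

Twelve values: whole-image SUV minimum/maximum/mean; mask voxel count,
26-connected component count and masked SUV minimum/maximum/mean on the
original grid; and voxel count plus masked SUV minimum/maximum/mean on the
interpolated (resampled) grid.  When resampling is disabled the
interpolated block repeats the original-grid statistics, so
``diagnostics_Mask-interpolated_Minimum`` is then simply the minimum SUV
inside the mask.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from ..errors import EmptyMaskError
from ..imaging import PETVolume, ROIMask

__all__ = ["diagnostics_features"]


def diagnostics_features(
    volume: PETVolume,
    mask: ROIMask,
    resampled: Optional[Tuple[PETVolume, ROIMask]] = None,
) -> Dict[str, float]:
    if mask.is_empty():
        raise EmptyMaskError("diagnostics need a non-empty mask")
    img = volume.values
    inside = img[mask.values]
    _, n_components = ndimage.label(mask.values, structure=np.ones((3, 3, 3), dtype=int))
    rvol, rmask = resampled if resampled is not None else (volume, mask)
    rinside = rvol.values[rmask.values]
    if rinside.size == 0:
        rinside = inside  # resampling collapsed the mask; fall back
        rmask = mask
    return {
        "diagnostics_Image-original_Minimum": float(img.min()),
        "diagnostics_Image-original_Maximum": float(img.max()),
        "diagnostics_Image-original_Mean": float(img.mean()),
        "diagnostics_Mask-original_VoxelNum": float(mask.n_voxels),
        "diagnostics_Mask-original_VolumeNum": float(n_components),
        "diagnostics_Mask-original_Minimum": float(inside.min()),
        "diagnostics_Mask-original_Maximum": float(inside.max()),
        "diagnostics_Mask-original_Mean": float(inside.mean()),
        "diagnostics_Mask-interpolated_VoxelNum": float(rmask.n_voxels),
        "diagnostics_Mask-interpolated_Minimum": float(rinside.min()),
        "diagnostics_Mask-interpolated_Maximum": float(rinside.max()),
        "diagnostics_Mask-interpolated_Mean": float(rinside.mean()),
    }
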