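"""Euclidean-ball morphology on voxel grids.

Dilation/erosion radii throughout the package are Euclidean distances in
voxels, computed with exact distance transforms, so "dilate by 8 voxels"
means every voxel within Euclidean distance 8 of the set.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_EPS = 1e-9


def dilate(mask: np.ndarray, radius_vox: float) -> np.ndarray:
    """Voxels within Euclidean distance ``radius_vox`` of the mask."""
    mask = np.asarray(mask, dtype=bool)
    if radius_vox <= 0:
        return mask.copy()
    if not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= radius_vox + _EPS


def erode(mask: np.ndarray, radius_vox: float) -> np.ndarray:
    """Voxels at Euclidean distance greater than ``radius_vox`` from the complement."""
    mask = np.asarray(mask, dtype=bool)
    if radius_vox <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask)
    return dist > radius_vox + _EPS
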