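"""Depth-from-surface maps shared by the network mask and the evaluation.

Depth is the Euclidean distance (mm) from a tissue voxel to the nearest
water voxel (the water-tissue interface), computed with a distance
transform. The same map defines the 1.5 cm segmentation shell, the
depth bins of the vessel-sO2 error analysis, and the superficial-skin
exclusion used for out-of-distribution scoring.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grids import GridSpec

__all__ = ["surface_depth_map", "shell_mask"]


def surface_depth_map(breast_mask: np.ndarray, voxel_size_mm: float) -> np.ndarray:
    """Distance (mm) to the nearest non-breast voxel; 0 outside the breast."""
    depth = ndimage.distance_transform_edt(breast_mask, sampling=voxel_size_mm)
    return np.asarray(depth, dtype=float)


def shell_mask(breast_mask: np.ndarray, grid: GridSpec,
               depth_mm: float = 15.0) -> np.ndarray:
    """Voxels within ``depth_mm`` of the breast surface (inclusive).

    Surface voxels (depth of one voxel step) are included; the default 15 mm
    shell is where photoacoustic signal remains recoverable before optical
    attenuation dominates.
    """
    if not np.any(breast_mask):
        raise ValueError("empty breast mask")
    depth = surface_depth_map(breast_mask, grid.voxel_size)
    return breast_mask & (depth <= depth_mm)
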