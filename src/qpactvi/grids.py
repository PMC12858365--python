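"""Voxel-grid geometry shared by all volumes in the pipeline.

Coordinates are voxel-centered, 0-based and in millimetres. The z axis is the
hemisphere symmetry axis: the chest-wall plane sits at the top of the volume
(z index 0) and the breast apex points toward larger z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Regular isotropic voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z).
    voxel_size : float
        Isotropic voxel edge length in mm.
    origin : tuple of float
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, ...]
    voxel_size: float
    origin: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be positive, got {shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        object.__setattr__(self, "shape", shape)
        origin = self.origin
        if origin is None:
            # default: grid centered on (0, 0) in x/y, z starting at 0
            origin = tuple(
                (-(s - 1) / 2.0 * self.voxel_size if ax < len(shape) - 1 else 0.0)
                for ax, s in enumerate(shape)
            )
        object.__setattr__(self, "origin", tuple(float(o) for o in origin))

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def extent_mm(self) -> tuple[float, ...]:
        return tuple(s * self.voxel_size for s in self.shape)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size**self.ndim)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates (mm) along one axis."""
        return self.origin[axis] + self.voxel_size * np.arange(self.shape[axis])

    def meshgrid(self) -> tuple[np.ndarray, ...]:
        """Voxel-center coordinate volumes, one per axis (indexing='ij')."""
        axes = [self.axis_coords(a) for a in range(self.ndim)]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def index_of(self, point_mm: np.ndarray) -> tuple[int, ...]:
        """Nearest voxel index of a physical point; clipped to the grid."""
        p = np.asarray(point_mm, dtype=float)
        idx = np.rint((p - np.asarray(self.origin)) / self.voxel_size).astype(int)
        idx = np.clip(idx, 0, np.asarray(self.shape) - 1)
        return tuple(int(i) for i in idx)
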