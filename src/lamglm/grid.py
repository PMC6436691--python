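"""Regular voxel grids and their world coordinates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid"]


@dataclass(frozen=True)
class Grid:
    """An axis-aligned voxel grid.

    World coordinates (mm) of the centre of voxel ``(i, j, k)`` are
    ``origin + voxel_size * (i, j, k)``; ``voxel_size`` may be a scalar
    (isotropic) or a 3-vector of edge lengths.
    """

    shape: tuple
    voxel_size: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        vs = np.broadcast_to(np.asarray(self.voxel_size, dtype=float), (3,)).copy()
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).copy())

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (NIfTI convention)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.voxel_size[axis] * np.arange(self.shape[axis])

    def meshgrid(self, axes=(0, 1, 2)):
        return np.meshgrid(*[self.axis_coords(a) for a in axes], indexing="ij")

    def upsampled(self, factor: int) -> "Grid":
        """Grid of ``factor**3`` sub-voxels tiling each voxel exactly."""
        factor = int(factor)
        return Grid(
            tuple(s * factor for s in self.shape),
            self.voxel_size / factor,
            self.origin - self.voxel_size * (factor - 1) / (2 * factor),
        )

    def downsampled(self, factor: int) -> "Grid":
        factor = int(factor)
        if any(s % factor for s in self.shape):
            raise ValueError(f"grid shape {self.shape} not divisible by {factor}")
        return Grid(
            tuple(s // factor for s in self.shape),
            self.voxel_size * factor,
            self.origin + self.voxel_size * (factor - 1) / 2,
        )
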