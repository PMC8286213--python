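"""The in-memory PET image container used by every pipeline stage.

A :class:`PetImage` is a 3D array of activity concentration (kBq/ml) on a
regular grid.  Array axes are (x, y, z) with axial slices along the third
axis; ``origin`` is the world coordinate (mm, phantom frame) of the centre
of voxel (0, 0, 0) — the voxel-centre convention shared by the NIfTI
writer in :mod:`petharm.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PetImage:
    voxels: np.ndarray  # (nx, ny, nz) float array, kBq/ml
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray  # (3,) mm, centre of voxel (0, 0, 0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("all spacing components must be > 0")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        n = self.voxels.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def index_to_world(self, idx) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(idx, dtype=float)

    def world_to_index(self, xyz) -> np.ndarray:
        """Fractional voxel index of a world position."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    def nearest_index(self, xyz) -> tuple[int, int, int]:
        idx = np.rint(self.world_to_index(xyz)).astype(int)
        return tuple(int(i) for i in idx)

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sparse meshgrid of world coordinates, broadcastable to the array."""
        xs = self.axis_coords(0)[:, None, None]
        ys = self.axis_coords(1)[None, :, None]
        zs = self.axis_coords(2)[None, None, :]
        return xs, ys, zs

    def total_activity_kbq(self) -> float:
        """Sum of voxel values times voxel volume (ml) — total activity in kBq."""
        return float(self.voxels.sum() * self.voxel_volume_mm3 / 1000.0)

    def copy_with(self, voxels: np.ndarray, **meta_updates) -> "PetImage":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return PetImage(voxels, self.spacing.copy(), self.origin.copy(), meta)
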