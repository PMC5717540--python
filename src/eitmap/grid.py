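"""Regular 3D voxel lattice geometry.

All physical coordinates in this package are micrometres (µm); volumes are
reported in mm³ where stated. The grid uses a voxel-centre convention: voxel
index ``(i, j, k)`` sits at ``origin_um + index * spacing_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3D lattice: the coordinate frame of all volumes.

    Parameters
    ----------
    dims : tuple of 3 int
        Number of voxels along x, y, z.
    spacing_um : tuple of 3 float
        Lattice spacing along each axis, µm.
    origin_um : tuple of 3 float
        Physical position of voxel (0, 0, 0), µm.
    """

    dims: tuple[int, int, int]
    spacing_um: tuple[float, float, float] = (25.0, 25.0, 25.0)
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing_um", tuple(float(s) for s in self.spacing_um))
        object.__setattr__(self, "origin_um", tuple(float(o) for o in self.origin_um))
        if len(self.dims) != 3 or len(self.spacing_um) != 3 or len(self.origin_um) != 3:
            raise ValueError("dims, spacing_um and origin_um must each have 3 entries")
        if any(d < 1 for d in self.dims):
            raise ValueError(f"all dims must be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"all spacings must be positive, got {self.spacing_um}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume_um3(self) -> float:
        """Volume of a single voxel in µm³ (product of the spacings)."""
        return float(np.prod(self.spacing_um))

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_volume_um3 * 1e-9

    def affine(self) -> np.ndarray:
        """4x4 affine mapping voxel indices to physical µm coordinates."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_um)
        aff[:3, 3] = self.origin_um
        return aff

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of the lattice along each axis (µm)."""
        return tuple(
            self.origin_um[a] + self.spacing_um[a] * np.arange(self.dims[a])
            for a in range(3)
        )

    def check_volume(self, volume: np.ndarray) -> np.ndarray:
        vol = np.asarray(volume)
        if vol.shape != self.dims:
            raise ValueError(f"volume shape {vol.shape} does not match grid dims {self.dims}")
        return vol
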