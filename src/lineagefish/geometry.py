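"""Voxel grids, spherical cell ROIs and cell geometry.

All physical coordinates are in micrometres (µm).  Voxel indices are 0-based;
arrays are laid out ``(z, y, x)``.  A voxel with index ``(k, j, i)`` has its
centre at ``((i + 0.5) * dx, (j + 0.5) * dy, (k + 0.5) * dz)``, i.e. voxels are
half-open boxes, but a z-slab is *inclusive* of every slice whose centre falls
inside the physical interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["VoxelGrid", "SphericalROI", "CellGeometry", "sphere_volume"]


@dataclass(frozen=True)
class VoxelGrid:
    """Physical sampling of an image stack.

    Parameters
    ----------
    dx, dy : float
        In-plane voxel size, µm.  Defaults correspond to a 63x confocal.
    dz : float
        z-slice spacing, µm (confocal stacks here use 500 nm).
    shape : tuple of int
        ``(nz, ny, nx)`` array dimensions.
    """

    dx: float = 0.12
    dy: float = 0.12
    dz: float = 0.5
    shape: tuple[int, int, int] = (16, 128, 128)

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel sizes must be positive")
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValueError("shape must be (nz, ny, nx) with positive entries")

    @property
    def nz(self) -> int:
        return self.shape[0]

    @property
    def ny(self) -> int:
        return self.shape[1]

    @property
    def nx(self) -> int:
        return self.shape[2]

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size ``(size_x, size_y, size_z)`` in µm."""
        return (self.nx * self.dx, self.ny * self.dy, self.nz * self.dz)

    @property
    def voxel_volume(self) -> float:
        return self.dx * self.dy * self.dz

    def z_slab(self, z_lo: float, z_hi: float) -> np.ndarray:
        """Indices of slices whose centres lie in ``[z_lo, z_hi]``."""
        centers = (np.arange(self.nz) + 0.5) * self.dz
        return np.nonzero((centers >= z_lo) & (centers <= z_hi))[0]

    def disk_mask(self, cx: float, cy: float, radius: float) -> np.ndarray:
        """Boolean ``(ny, nx)`` mask of voxel centres within ``radius`` of (cx, cy)."""
        xs = (np.arange(self.nx) + 0.5) * self.dx
        ys = (np.arange(self.ny) + 0.5) * self.dy
        dx2 = (xs[None, :] - cx) ** 2
        dy2 = (ys[:, None] - cy) ** 2
        return dx2 + dy2 <= radius**2


@dataclass(frozen=True)
class SphericalROI:
    """A cell modelled as a sphere: centre ``(x, y, z)`` and diameter, in µm."""

    center: tuple[float, float, float]
    diameter: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def within(self, grid: VoxelGrid) -> bool:
        ex, ey, ez = grid.extent
        x, y, z = self.center
        r = self.radius
        return (
            x - r >= 0 and x + r <= ex
            and y - r >= 0 and y + r <= ey
            and z - r >= 0 and z + r <= ez
        )

    def check_within(self, grid: VoxelGrid) -> None:
        """Raise with the offending bound if the sphere leaves the volume."""
        ex, ey, ez = grid.extent
        x, y, z = self.center
        r = self.radius
        for axis, lo, hi, ext in (
            ("x", x - r, x + r, ex),
            ("y", y - r, y + r, ey),
            ("z", z - r, z + r, ez),
        ):
            if lo < 0:
                raise ValueError(
                    f"ROI extends past the lower {axis} bound ({lo:.3f} µm < 0)"
                )
            if hi > ext:
                raise ValueError(
                    f"ROI extends past the upper {axis} bound "
                    f"({hi:.3f} µm > {ext:.3f} µm)"
                )


def sphere_volume(diameter: float) -> float:
    """Volume of a sphere of the given diameter, µm³: (π/6)·d³.

    Cells are treated as spheres of their measured average diameter; e.g. a
    6.0 µm cell has a volume of 113 µm³ and a 3.5 µm cell 22 µm³ (nearest
    integer).
    """
    if diameter < 0:
        raise ValueError("diameter must be non-negative")
    return math.pi / 6.0 * diameter**3


@dataclass(frozen=True)
class CellGeometry:
    """Diameter-derived geometry of a (spherical) cell."""

    diameter: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("cell diameter must be positive")

    @property
    def volume(self) -> float:
        return sphere_volume(self.diameter)
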