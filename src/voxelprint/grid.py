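"""Print-volume grid definition.

The print volume is an axis-aligned box of ``dims`` voxels with uniform
``spacing`` (mm per voxel along x, y, z) anchored at ``origin``, the world
position of the outer corner of voxel (0, 0, 0).  Sampling is voxel-centered:
voxel (i, j, k) sits at ``origin + (i + 0.5, j + 0.5, k + 0.5) * spacing``.
World extents are half-open; z increases with layer number (bottom-up).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel lattice for the print volume.

    Parameters
    ----------
    dims : tuple of int
        Voxel counts ``(nx, ny, nz)``; all >= 1.
    spacing : tuple of float
        Edge length of a voxel in mm along x, y, z; all > 0.
    origin : tuple of float
        World-space (mm) position of the corner of voxel ``(0, 0, 0)``.
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(dims) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("dims, spacing and origin must be length-3")
        if any(d < 1 for d in dims):
            raise ValueError(f"all dims must be >= 1, got {dims}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def extent(self) -> tuple[float, float, float]:
        """World extent (mm) along each axis: dim * spacing."""
        return tuple(d * s for d, s in zip(self.dims, self.spacing))

    @property
    def world_max(self) -> tuple[float, float, float]:
        return tuple(o + e for o, e in zip(self.origin, self.extent))

    def voxel_centers_1d(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (mm)."""
        n = self.dims[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def voxel_center(self, index: tuple[int, int, int]) -> tuple[float, float, float]:
        return tuple(
            self.origin[a] + (index[a] + 0.5) * self.spacing[a] for a in range(3)
        )

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates (n, 3) to integer voxel indices (floor)."""
        pts = np.asarray(points, dtype=float)
        rel = (pts - np.asarray(self.origin)) / np.asarray(self.spacing)
        return np.floor(rel).astype(np.int64)

    def contains_box(self, lo, hi) -> bool:
        """True if the world-space box [lo, hi] lies inside the grid extent."""
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        return bool(
            np.all(lo >= np.asarray(self.origin) - 1e-9)
            and np.all(hi <= np.asarray(self.world_max) + 1e-9)
        )
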