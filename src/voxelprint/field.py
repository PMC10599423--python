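"""Multichannel voxel fields and hierarchical compositing.

The print volume is represented by two channels on a shared grid: a geometry
channel (solid/void occupancy) and a color channel holding the material
mixing color (RGB) plus the clear-material fraction per solid voxel.
Multiple data sources (anatomy, functional overlays, voxelized vector data)
are composited hierarchically: later layers supersede earlier ones, either
color-only or color-and-geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .grid import GridSpec
from .transfer import ColorLUT, OpacityCurve, compensate_transparency
from .volume import ScalarVolume

__all__ = [
    "MultiChannelVoxelField",
    "OverlayLayer",
    "OverlayStack",
    "from_scalar_volume",
    "overlay_fields",
    "make_clear_hull",
]

# 26-connected structuring element (watertight shells / components)
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class MultiChannelVoxelField:
    """Geometry + color + clear-fraction channels on a print grid.

    ``geometry`` is the per-voxel solid/void boolean; ``color`` (RGB in
    [0, 1]) and ``clear_fraction`` (in [0, 1]) are meaningful only where
    solid.  Array axis order is (x, y, z), with an extra trailing axis of 3
    for color.
    """

    grid: GridSpec
    geometry: np.ndarray = dc_field(repr=False)
    color: np.ndarray = dc_field(repr=False)
    clear_fraction: np.ndarray = dc_field(repr=False)

    def __post_init__(self) -> None:
        self.geometry = np.asarray(self.geometry, dtype=bool)
        self.color = np.asarray(self.color, dtype=np.float64)
        self.clear_fraction = np.asarray(self.clear_fraction, dtype=np.float64)
        dims = self.grid.dims
        if self.geometry.shape != dims:
            raise ValueError("geometry shape does not match grid dims")
        if self.color.shape != dims + (3,):
            raise ValueError("color shape must be dims + (3,)")
        if self.clear_fraction.shape != dims:
            raise ValueError("clear_fraction shape does not match grid dims")
        solid_cf = self.clear_fraction[self.geometry]
        if solid_cf.size and (solid_cf.min() < -1e-9 or solid_cf.max() > 1 + 1e-9):
            raise ValueError("clear_fraction must lie in [0, 1] on solid voxels")

    @classmethod
    def empty(cls, grid: GridSpec) -> "MultiChannelVoxelField":
        """All-void field on ``grid``."""
        return cls(
            grid,
            np.zeros(grid.dims, dtype=bool),
            np.zeros(grid.dims + (3,)),
            np.zeros(grid.dims),
        )

    @property
    def solid_count(self) -> int:
        return int(self.geometry.sum())

    def copy(self) -> "MultiChannelVoxelField":
        return MultiChannelVoxelField(
            self.grid,
            self.geometry.copy(),
            self.color.copy(),
            self.clear_fraction.copy(),
        )


OverrideMode = Literal["color-only", "color-and-geometry"]


@dataclass(frozen=True)
class OverlayLayer:
    field: MultiChannelVoxelField
    mode: OverrideMode = "color-only"

    def __post_init__(self) -> None:
        if self.mode not in ("color-only", "color-and-geometry"):
            raise ValueError(f"unknown override mode {self.mode!r}")


@dataclass(frozen=True)
class OverlayStack:
    """Ordered compositing stack; the first layer is the base model.

    Order is significant: later layers supersede earlier ones where solid.
    """

    layers: tuple[OverlayLayer, ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("an OverlayStack needs at least one layer")
        g0 = self.layers[0].field.grid
        for lay in self.layers[1:]:
            if lay.field.grid != g0:
                raise ValueError(
                    f"overlay grid mismatch: {lay.field.grid} != {g0}"
                )

    @classmethod
    def of(cls, base: MultiChannelVoxelField, *overlays) -> "OverlayStack":
        """Convenience builder: ``of(base, (field, mode), field, ...)``.

        Bare fields default to color-only override.
        """
        layers = [OverlayLayer(base, "color-and-geometry")]
        for ov in overlays:
            if isinstance(ov, OverlayLayer):
                layers.append(ov)
            elif isinstance(ov, tuple):
                layers.append(OverlayLayer(*ov))
            else:
                layers.append(OverlayLayer(ov))
        return cls(tuple(layers))


def from_scalar_volume(
    volume: ScalarVolume,
    threshold_low: float,
    threshold_high: float,
    lut: ColorLUT,
    opacity_curve: OpacityCurve = OpacityCurve(),
    keep_largest_component: bool = False,
) -> MultiChannelVoxelField:
    """Threshold a scalar volume into a colored voxel field.

    A voxel is solid iff its normalized intensity lies in the inclusive band
    ``[threshold_low, threshold_high]``.  Solid voxels take the LUT color at
    their intensity; the LUT opacity is converted to a clear-material
    fraction through ``opacity_curve``.  With ``keep_largest_component`` only
    the largest 26-connected solid component is retained (e.g. the blood pool
    or brain after masking).
    """
    if threshold_low > threshold_high:
        raise ValueError(
            f"threshold_low ({threshold_low}) > threshold_high ({threshold_high})"
        )
    x = volume.intensities
    solid = (x >= threshold_low) & (x <= threshold_high)
    if not solid.any():
        warnings.warn(
            "thresholding produced an empty solid set; returning an all-void field",
            stacklevel=2,
        )
        return MultiChannelVoxelField.empty(volume.grid)

    lo, hi = lut.domain
    xmin, xmax = float(x[solid].min()), float(x[solid].max())
    if xmin < lo - 1e-9 or xmax > hi + 1e-9:
        raise ValueError(
            f"LUT domain [{lo}, {hi}] does not cover the volume's intensity "
            f"range [{xmin:.4g}, {xmax:.4g}]"
        )

    if keep_largest_component:
        labels, nlab = ndimage.label(solid, structure=_STRUCT26)
        if nlab > 1:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            solid = labels == int(counts.argmax())

    rgb, alpha = lut(x)
    clear = compensate_transparency(alpha, opacity_curve)
    out = MultiChannelVoxelField.empty(volume.grid)
    out.geometry = solid
    out.color = np.where(solid[..., None], rgb, 0.0)
    out.clear_fraction = np.where(solid, clear, 0.0)
    return out


def overlay_fields(stack: OverlayStack) -> MultiChannelVoxelField:
    """Composite an overlay stack with last-wins supersede semantics.

    The result geometry is the union of the base geometry and all
    color-and-geometry layers.  Per voxel, color and clear fraction come from
    the last layer in the stack that is solid there; base attributes are
    retained where no overlay is solid.  Color-only layers paint existing
    solid voxels but never extend the geometry.
    """
    base = stack.layers[0].field
    geometry = base.geometry.copy()
    for lay in stack.layers[1:]:
        if lay.mode == "color-and-geometry":
            geometry |= lay.field.geometry

    color = np.where(base.geometry[..., None], base.color, 0.0)
    clear = np.where(base.geometry, base.clear_fraction, 0.0)
    for lay in stack.layers[1:]:
        paint = lay.field.geometry & geometry
        color = np.where(paint[..., None], lay.field.color, color)
        clear = np.where(paint, lay.field.clear_fraction, clear)
    # scrub attributes on void voxels
    color = np.where(geometry[..., None], color, 0.0)
    clear = np.where(geometry, clear, 0.0)
    return MultiChannelVoxelField(base.grid, geometry, color, clear)


def make_clear_hull(
    field: MultiChannelVoxelField,
    shell_voxels: int = 1,
    hull_color: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> MultiChannelVoxelField:
    """Enclose the solid set in a clear shell of ``shell_voxels`` thickness.

    The hull is the 26-connected morphological dilation of the solid set
    minus the solid set itself; hull voxels get clear_fraction 1 and a white
    reference color.  Interior voxels are unchanged.  A minimal one-voxel
    shell stands in for an infinitely thin enclosure, which a voxel lattice
    cannot represent.
    """
    if shell_voxels < 1:
        raise ValueError("shell_voxels must be >= 1")
    if not field.geometry.any():
        warnings.warn("field has no solid voxels; nothing to enclose", stacklevel=2)
        return field.copy()

    k = int(shell_voxels)
    padded = np.pad(field.geometry, k)
    dilated = ndimage.binary_dilation(padded, structure=_STRUCT26, iterations=k)
    # any dilated voxel in the pad margin would fall outside the grid
    core = np.zeros_like(dilated)
    core[k:-k, k:-k, k:-k] = True
    if (dilated & ~core).any():
        raise ValueError(
            f"a {k}-voxel shell exceeds the grid bounds; pad the grid by at "
            f"least {k} voxels before adding a hull"
        )
    hull = dilated[k:-k, k:-k, k:-k] & ~field.geometry

    out = field.copy()
    out.geometry = field.geometry | hull
    out.color[hull] = np.asarray(hull_color, dtype=float)
    out.clear_fraction[hull] = 1.0
    return out
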