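"""Layer subdivision and rasterization of the dithered material volume.

The printer consumes one raster per deposited layer.  The material volume is
subdivided into fixed-thickness blocks (default 30 μm); each block is
rasterized by nearest-voxel lookup at pixel centers at the block's
mid-height, encoding every material as its exact palette RGBA code (void is
alpha 0).  Very fine curves can additionally be rasterized directly into
slices at print time from interval-tree stabbing queries, bypassing
full-grid voxelization.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .dither import VOID, MaterialPalette, MaterialVolume
from .grid import GridSpec
from .tracts import Segment
from ._geometry import points_in_sweep

__all__ = [
    "DEFAULT_LAYER_UM",
    "DEFAULT_PITCH_MM",
    "SliceStack",
    "slice_material_volume",
    "rasterize_segments_into_slice",
    "stack_to_volume",
]

DEFAULT_LAYER_UM = 30.0
# xy droplet pitch of a 600 x 300 dpi print-head class
DEFAULT_PITCH_MM = (25.4 / 600.0, 25.4 / 300.0)


@dataclass
class SliceStack:
    """Ordered per-layer RGBA8 rasters plus printing metadata.

    Rasters are (ny, nx, 4) uint8 arrays; row index is the y pixel index,
    column index the x pixel index; layer 0 is the bottom layer.
    """

    layers: list[np.ndarray]
    layer_thickness_um: float
    pixel_pitch_mm: tuple[float, float]
    palette: MaterialPalette
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a slice stack needs at least one layer")
        if self.layer_thickness_um <= 0:
            raise ValueError("layer thickness must be > 0")
        if any(p <= 0 for p in self.pixel_pitch_mm):
            raise ValueError("pixel pitch must be > 0")
        shape0 = self.layers[0].shape
        for lay in self.layers:
            if lay.shape != shape0 or lay.ndim != 3 or lay.shape[2] != 4:
                raise ValueError("all rasters must share one (ny, nx, 4) shape")
        self.layers = [np.ascontiguousarray(l, dtype=np.uint8) for l in self.layers]

    @property
    def layer_count(self) -> int:
        return len(self.layers)

    @property
    def raster_shape(self) -> tuple[int, int]:
        return self.layers[0].shape[:2]


def slice_material_volume(
    volume: MaterialVolume,
    layer_thickness_um: float = DEFAULT_LAYER_UM,
    pixel_pitch_mm: tuple[float, float] | None = None,
    resample: str | None = "nearest",
) -> SliceStack:
    """Subdivide a material volume into fixed-thickness raster layers.

    ``layer_count = ceil(z_extent / layer_thickness)``; each layer samples
    the volume by nearest-voxel lookup at pixel centers at the layer's
    mid-height.  With ``pixel_pitch_mm=None`` the grid's xy spacing is used,
    making slicing lossless (exactly one pixel per voxel column).  A pitch
    different from the grid spacing requires ``resample="nearest"``
    (the default); pass ``resample=None`` to forbid implicit resampling.
    """
    if layer_thickness_um <= 0:
        raise ValueError("layer thickness must be > 0")
    grid = volume.grid
    pitch = tuple(pixel_pitch_mm) if pixel_pitch_mm else grid.spacing[:2]
    if any(p <= 0 for p in pitch):
        raise ValueError("pixel pitch must be > 0")
    matches_grid = np.allclose(pitch, grid.spacing[:2], rtol=1e-9, atol=1e-12)
    if not matches_grid and resample != "nearest":
        raise ValueError(
            f"pixel pitch {pitch} differs from grid xy spacing "
            f"{grid.spacing[:2]} and no resampling policy is set; pass "
            'resample="nearest" to sample by nearest voxel'
        )

    th_mm = layer_thickness_um / 1000.0
    ex, ey, ez = grid.extent
    n_layers = int(np.ceil(ez / th_mm - 1e-9))
    nxp = int(np.ceil(ex / pitch[0] - 1e-9))
    nyp = int(np.ceil(ey / pitch[1] - 1e-9))

    codes = np.array(
        [m.rgba_code for m in volume.palette] + [(0, 0, 0, 0)], dtype=np.uint8
    )  # last row encodes void

    # nearest-voxel index per pixel center (same for every layer)
    px = (np.arange(nxp) + 0.5) * pitch[0]
    py = (np.arange(nyp) + 0.5) * pitch[1]
    ix = np.clip((px / grid.spacing[0]).astype(np.int64), 0, grid.dims[0] - 1)
    iy = np.clip((py / grid.spacing[1]).astype(np.int64), 0, grid.dims[1] - 1)

    layers = []
    for layer in range(n_layers):
        zmid = (layer + 0.5) * th_mm
        iz = int(np.clip(np.floor(zmid / grid.spacing[2]), 0, grid.dims[2] - 1))
        plane = volume.assignment[:, :, iz]  # (nx, ny)
        sampled = plane[np.ix_(ix, iy)]  # (nxp, nyp)
        raster = codes[np.where(sampled == VOID, len(volume.palette), sampled)]
        layers.append(np.ascontiguousarray(raster.transpose(1, 0, 2)))  # (ny, nx, 4)

    return SliceStack(
        layers=layers,
        layer_thickness_um=layer_thickness_um,
        pixel_pitch_mm=pitch,
        palette=volume.palette,
        origin=grid.origin,
    )


def rasterize_segments_into_slice(
    raster: np.ndarray,
    segments: list[Segment],
    z: float,
    pixel_pitch_mm: tuple[float, float],
    palette: MaterialPalette,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Draw curve segments directly into one slice raster at height ``z``.

    Pixels whose centers lie within a segment's swept cross-section at this
    height take the palette code nearest (Euclidean RGB) to the segment
    color there (endpoint colors linearly interpolated along the segment).
    Curve pixels supersede whatever the raster already holds, mirroring the
    hierarchical overlay semantics.  Returns the mutated raster.
    """
    if raster.ndim != 3 or raster.shape[2] != 4:
        raise ValueError("raster must be (ny, nx, 4) RGBA8")
    ny, nx = raster.shape[:2]
    pxs = origin[0] + (np.arange(nx) + 0.5) * pixel_pitch_mm[0]
    pys = origin[1] + (np.arange(ny) + 0.5) * pixel_pitch_mm[1]
    pal_rgb = palette.display_rgbs
    codes = np.array([m.rgba_code for m in palette], dtype=np.uint8)

    for seg in segments:
        a = np.asarray(seg.a)
        b = np.asarray(seg.b)
        pad = seg.radius + 0.5 * float(np.hypot(*pixel_pitch_mm))
        lox, hix = min(a[0], b[0]) - pad, max(a[0], b[0]) + pad
        loy, hiy = min(a[1], b[1]) - pad, max(a[1], b[1]) + pad
        i0, i1 = np.searchsorted(pxs, lox), np.searchsorted(pxs, hix, "right")
        j0, j1 = np.searchsorted(pys, loy), np.searchsorted(pys, hiy, "right")
        if i0 >= i1 or j0 >= j1:
            continue
        gx, gy = np.meshgrid(pxs[i0:i1], pys[j0:j1], indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel(), np.full(gx.size, float(z))], axis=1)
        inside = points_in_sweep(
            pts, a, b, seg.radius, seg.cross_section, seg.n1, seg.n2
        )
        if not inside.any():
            continue
        ab = b - a
        denom = float(ab @ ab)
        t = (
            np.clip((pts[inside] - a) @ ab / denom, 0.0, 1.0)
            if denom > 0
            else np.zeros(int(inside.sum()))
        )
        col = (1 - t)[:, None] * np.asarray(seg.color_a) + t[:, None] * np.asarray(
            seg.color_b
        )
        # snap each curve pixel to the nearest palette code
        d2 = ((col[:, None, :] - pal_rgb[None, :, :]) ** 2).sum(axis=2)
        chosen = codes[d2.argmin(axis=1)]
        ii, jj = np.nonzero(inside.reshape(gx.shape))
        raster[jj + j0, ii + i0] = chosen
    return raster


def stack_to_volume(stack: SliceStack) -> MaterialVolume:
    """Reassemble a slice stack into a material volume (verification inverse).

    Exact inverse of :func:`slice_material_volume` whenever the pitch and
    layer thickness match the source grid spacing.
    """
    ny, nx = stack.raster_shape
    nz = stack.layer_count

    def pack(rgba: np.ndarray) -> np.ndarray:
        r = rgba.astype(np.uint32)
        return (r[..., 0] << 24) | (r[..., 1] << 16) | (r[..., 2] << 8) | r[..., 3]

    pal_keys = pack(np.array([m.rgba_code for m in stack.palette], dtype=np.uint8))
    order = np.argsort(pal_keys)
    sorted_keys = pal_keys[order]

    assignment = np.full((nx, ny, nz), VOID, dtype=np.int16)
    for k, raster in enumerate(stack.layers):
        if raster.shape[:2] != (ny, nx):
            raise ValueError("inconsistent raster dimensions in stack")
        plane = raster.transpose(1, 0, 2)  # (nx, ny, 4)
        keys = pack(plane)
        nonvoid = plane[..., 3] != 0
        pos = np.searchsorted(sorted_keys, keys)
        pos_c = np.clip(pos, 0, len(sorted_keys) - 1)
        known = sorted_keys[pos_c] == keys
        bad = nonvoid & ~known
        if bad.any():
            bi, bj = np.argwhere(bad)[0]
            raise ValueError(
                f"layer {k}: pixel RGBA {tuple(int(v) for v in plane[bi, bj])} "
                f"at (x={bi}, y={bj}) not in palette"
            )
        idx = order[pos_c].astype(np.int16)
        assignment[:, :, k] = np.where(nonvoid, idx, VOID)
    grid = GridSpec(
        dims=(nx, ny, nz),
        spacing=(
            stack.pixel_pitch_mm[0],
            stack.pixel_pitch_mm[1],
            stack.layer_thickness_um / 1000.0,
        ),
        origin=stack.origin,
    )
    return MaterialVolume(grid, stack.palette, assignment)
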