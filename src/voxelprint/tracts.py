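"""Colored polylines (streamlines, tractography fibers) and their voxelization.

Vector physiology data arrive as polylines with per-vertex RGB (velocity- or
orientation-encoded) plus a thickness and cross-section shape, or as closed
colored surface meshes.  Both are converted to voxel sets whose voxels
inherit the color of the nearest vertex.  For slice-time rasterization of
very fine lines, segments are organized in an interval tree over their
(radius-inflated) z-extents so each print layer only inspects the segments
it can intersect.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from intervaltree import IntervalTree
from scipy.spatial import cKDTree

from ._geometry import grid_in_mesh, points_in_sweep, transport_frames
from .field import MultiChannelVoxelField
from .grid import GridSpec

__all__ = [
    "PT_TO_MM",
    "ColoredMesh",
    "Polyline",
    "ColoredPolylineSet",
    "Segment",
    "SegmentIntervalTree",
    "build_interval_tree",
    "query_slice_segments",
    "voxelize_polylines",
    "voxelize_colored_mesh",
]

PT_TO_MM = 25.4 / 72.0  # printer's point

_CROSS_SECTIONS = ("circle", "triangle", "square")


@dataclass
class ColoredMesh:
    """Triangle mesh with per-vertex RGB color (e.g. streamline surfaces)."""

    vertices: np.ndarray  # (n, 3) mm
    colors: np.ndarray  # (n, 3) in [0, 1]
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.colors = np.asarray(self.colors, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.colors) != len(self.vertices):
            raise ValueError("every vertex must carry a color")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")


@dataclass
class Polyline:
    """One identified polyline with per-vertex colors.

    ``thickness`` is the swept diameter in mm (use :func:`pt_to_mm` or the
    ``thickness_pt`` argument of parsers for printer's points).
    """

    id: int
    vertices: np.ndarray  # (n, 3) mm
    vertex_colors: np.ndarray  # (n, 3) in [0, 1]
    thickness: float = 1.0 * PT_TO_MM
    cross_section: str = "circle"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.vertex_colors = np.asarray(self.vertex_colors, dtype=float).reshape(-1, 3)
        if len(self.vertices) < 2:
            raise ValueError(f"polyline {self.id} needs >= 2 vertices")
        if len(self.vertex_colors) != len(self.vertices):
            raise ValueError(f"polyline {self.id}: one color per vertex required")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")
        if self.cross_section not in _CROSS_SECTIONS:
            raise ValueError(
                f"cross_section must be one of {_CROSS_SECTIONS}, "
                f"got {self.cross_section!r}"
            )

    @property
    def radius(self) -> float:
        return self.thickness / 2.0


@dataclass
class ColoredPolylineSet:
    polylines: list[Polyline] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.polylines]
        if len(set(ids)) != len(ids):
            raise ValueError("polyline ids must be unique")

    def __len__(self) -> int:
        return len(self.polylines)

    def __iter__(self):
        return iter(self.polylines)

    def bounds(self, inflate: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """World bounding box of all vertices, optionally radius-inflated."""
        if not self.polylines:
            raise ValueError("empty polyline set has no bounds")
        los, his = [], []
        for p in self.polylines:
            r = p.radius if inflate else 0.0
            los.append(p.vertices.min(axis=0) - r)
            his.append(p.vertices.max(axis=0) + r)
        return np.min(los, axis=0), np.max(his, axis=0)

    def all_vertices(self) -> tuple[np.ndarray, np.ndarray]:
        """All vertices and colors concatenated in (polyline, vertex) order.

        The concatenation order defines the global tie-break for
        nearest-vertex color inheritance: lowest polyline first, then lowest
        vertex index.
        """
        order = sorted(self.polylines, key=lambda p: p.id)
        verts = np.concatenate([p.vertices for p in order], axis=0)
        cols = np.concatenate([p.vertex_colors for p in order], axis=0)
        return verts, cols


@dataclass(frozen=True)
class Segment:
    """One polyline segment with endpoint attributes and sweep frame."""

    polyline_id: int
    a: tuple[float, float, float]
    b: tuple[float, float, float]
    color_a: tuple[float, float, float]
    color_b: tuple[float, float, float]
    radius: float
    cross_section: str = "circle"
    n1: tuple[float, float, float] = (1.0, 0.0, 0.0)
    n2: tuple[float, float, float] = (0.0, 1.0, 0.0)

    @property
    def z_interval(self) -> tuple[float, float]:
        """Radius-inflated closed z-extent [min z - r, max z + r]."""
        zlo = min(self.a[2], self.b[2]) - self.radius
        zhi = max(self.a[2], self.b[2]) + self.radius
        return zlo, zhi


def _segments_of(line: Polyline) -> list[Segment]:
    _, n1, n2 = transport_frames(line.vertices)
    segs = []
    for i in range(len(line.vertices) - 1):
        segs.append(
            Segment(
                polyline_id=line.id,
                a=tuple(line.vertices[i]),
                b=tuple(line.vertices[i + 1]),
                color_a=tuple(line.vertex_colors[i]),
                color_b=tuple(line.vertex_colors[i + 1]),
                radius=line.radius,
                cross_section=line.cross_section,
                n1=tuple(n1[i]),
                n2=tuple(n2[i]),
            )
        )
    return segs


class SegmentIntervalTree:
    """Interval tree over radius-inflated segment z-extents.

    Supports stabbing queries ("which segments can intersect the horizontal
    plane at z") in logarithmic-plus-output time, which keeps per-slice
    intersection work proportional to the segments actually crossing the
    slice rather than the whole tract set.
    """

    def __init__(self, segments: list[Segment]):
        self.segments = list(segments)
        self._tree = IntervalTree()
        for idx, seg in enumerate(self.segments):
            zlo, zhi = seg.z_interval
            # pad the upper bound one ulp so the half-open library interval
            # behaves as the closed interval [zlo, zhi]
            self._tree.addi(zlo, np.nextafter(zhi, np.inf), idx)

    def __len__(self) -> int:
        return len(self.segments)

    def stab(self, z: float) -> list[Segment]:
        hits = sorted(iv.data for iv in self._tree.at(float(z)))
        return [self.segments[i] for i in hits]


def build_interval_tree(lines: ColoredPolylineSet) -> SegmentIntervalTree:
    """Split polylines into segments and index them by z-interval."""
    if len(lines) == 0:
        raise ValueError("cannot build an interval tree from an empty set")
    segs: list[Segment] = []
    for line in lines:
        segs.extend(_segments_of(line))
    return SegmentIntervalTree(segs)


def query_slice_segments(tree: SegmentIntervalTree, z: float) -> list[Segment]:
    """All segments whose radius-inflated z-interval contains ``z``."""
    return tree.stab(z)


def _nearest_vertex_colors(
    points: np.ndarray, vertices: np.ndarray, colors: np.ndarray
) -> np.ndarray:
    """Nearest-vertex color per point; distance ties -> lowest vertex index."""
    kdt = cKDTree(vertices)
    k = min(8, len(vertices))
    dist, idx = kdt.query(points, k=k)
    if k == 1:
        return colors[idx]
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    tied = dist <= dist[:, :1] + 1e-9
    chosen = np.where(tied, idx, len(vertices)).min(axis=1)
    return colors[chosen]


def voxelize_polylines(
    lines: ColoredPolylineSet, grid: GridSpec
) -> MultiChannelVoxelField:
    """Sweep each polyline's cross-section through the grid.

    A voxel is solid iff its center lies within the swept profile of some
    segment (circle: distance to the centerline <= radius, with rounded
    caps; square/triangle: the profile in the parallel-transported frame,
    flat caps).  Each solid voxel inherits the color of the globally nearest
    polyline vertex (ties broken toward the lowest vertex of the lowest
    polyline id).  The clear fraction of tube voxels is 0 (fully colored).
    """
    lo, hi = lines.bounds(inflate=True)
    if not grid.contains_box(lo, hi):
        raise ValueError(
            "grid too small for the polyline set: need world bounds "
            f"[{lo.tolist()}, {hi.tolist()}], grid covers "
            f"[{list(grid.origin)}, {list(grid.world_max)}]"
        )

    xs = grid.voxel_centers_1d(0)
    ys = grid.voxel_centers_1d(1)
    zs = grid.voxel_centers_1d(2)
    solid = np.zeros(grid.dims, dtype=bool)
    half_diag = 0.5 * float(np.linalg.norm(grid.spacing))

    for line in lines:
        for seg in _segments_of(line):
            a = np.asarray(seg.a)
            b = np.asarray(seg.b)
            pad = seg.radius + half_diag
            blo = np.minimum(a, b) - pad
            bhi = np.maximum(a, b) + pad
            i0, i1 = np.searchsorted(xs, blo[0]), np.searchsorted(xs, bhi[0], "right")
            j0, j1 = np.searchsorted(ys, blo[1]), np.searchsorted(ys, bhi[1], "right")
            k0, k1 = np.searchsorted(zs, blo[2]), np.searchsorted(zs, bhi[2], "right")
            if i0 >= i1 or j0 >= j1 or k0 >= k1:
                continue
            gx, gy, gz = np.meshgrid(
                xs[i0:i1], ys[j0:j1], zs[k0:k1], indexing="ij"
            )
            pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
            inside = points_in_sweep(
                pts, a, b, seg.radius, seg.cross_section, seg.n1, seg.n2
            )
            solid[i0:i1, j0:j1, k0:k1] |= inside.reshape(gx.shape)

    out = MultiChannelVoxelField.empty(grid)
    out.geometry = solid
    if solid.any():
        verts, cols = lines.all_vertices()
        ii, jj, kk = np.nonzero(solid)
        centers = np.stack([xs[ii], ys[jj], zs[kk]], axis=1)
        out.color[ii, jj, kk] = _nearest_vertex_colors(centers, verts, cols)
    return out


def voxelize_colored_mesh(mesh: ColoredMesh, grid: GridSpec) -> MultiChannelVoxelField:
    """Fill a closed colored surface mesh with nearest-vertex-colored voxels.

    The mesh must be watertight (every edge shared by exactly two faces);
    voxels whose centers fall inside the surface (generalized winding number
    > 1/2) become solid and inherit the color of the nearest mesh vertex
    (ties -> lowest vertex index).
    """
    open_edges = _open_edge_count(mesh.faces)
    if open_edges:
        raise ValueError(
            f"mesh is not watertight: {open_edges} open (boundary) edges"
        )
    xs = grid.voxel_centers_1d(0)
    ys = grid.voxel_centers_1d(1)
    zs = grid.voxel_centers_1d(2)
    # restrict the inside test to the mesh bounding box
    blo = mesh.vertices.min(axis=0)
    bhi = mesh.vertices.max(axis=0)
    i0, i1 = np.searchsorted(xs, blo[0]), np.searchsorted(xs, bhi[0], "right")
    j0, j1 = np.searchsorted(ys, blo[1]), np.searchsorted(ys, bhi[1], "right")
    k0, k1 = np.searchsorted(zs, blo[2]), np.searchsorted(zs, bhi[2], "right")
    out = MultiChannelVoxelField.empty(grid)
    if i0 >= i1 or j0 >= j1 or k0 >= k1:
        return out
    inside = grid_in_mesh(xs[i0:i1], ys[j0:j1], zs[k0:k1], mesh.vertices, mesh.faces)
    out.geometry[i0:i1, j0:j1, k0:k1] = inside
    if out.geometry.any():
        ii, jj, kk = np.nonzero(out.geometry)
        centers = np.stack([xs[ii], ys[jj], zs[kk]], axis=1)
        out.color[ii, jj, kk] = _nearest_vertex_colors(
            centers, mesh.vertices, mesh.colors
        )
    return out


def _open_edge_count(faces: np.ndarray) -> int:
    edges = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int((counts != 2).sum())
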