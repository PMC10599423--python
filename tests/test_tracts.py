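"""Interval-tree, tube-sweep and mesh voxelization tests."""

import numpy as np
import pytest

from voxelprint import (
    ColoredMesh,
    ColoredPolylineSet,
    GridSpec,
    PT_TO_MM,
    Polyline,
    build_interval_tree,
    query_slice_segments,
    voxelize_colored_mesh,
    voxelize_polylines,
)


def _random_lines(rng, n_lines=5, n_pts=4, box=20.0, thickness=0.8):
    lines = []
    for i in range(n_lines):
        verts = rng.uniform(2.0, box - 2.0, size=(n_pts, 3))
        cols = rng.random((n_pts, 3))
        lines.append(Polyline(i, verts, cols, thickness))
    return ColoredPolylineSet(lines)


def _stab_oracle(tree, z):
    """Linear scan over all segments with closed-interval membership."""
    out = []
    for i, seg in enumerate(tree.segments):
        zlo, zhi = seg.z_interval
        if zlo <= z <= zhi:
            out.append(i)
    return out


class TestIntervalTree:
    def test_segment_count_is_vertices_minus_one(self):
        line = Polyline(0, [(0, 0, 0), (0, 0, 1), (0, 0, 2)], [(1, 0, 0)] * 3, 0.5)
        tree = build_interval_tree(ColoredPolylineSet([line]))
        assert len(tree) == 2

    def test_basic_stab_and_disjoint_plane(self):
        line = Polyline(0, [(0, 0, 0), (0, 0, 1)], [(1, 0, 0)] * 2, 1e-9)
        tree = build_interval_tree(ColoredPolylineSet([line]))
        assert len(query_slice_segments(tree, 0.5)) == 1
        assert query_slice_segments(tree, 5.0) == []

    def test_interval_inflated_by_radius(self):
        line = Polyline(0, [(0, 0, 0), (0, 0, 1)], [(1, 0, 0)] * 2, 0.4)  # r = 0.2
        tree = build_interval_tree(ColoredPolylineSet([line]))
        assert len(query_slice_segments(tree, 1.1)) == 1
        assert len(query_slice_segments(tree, 1.2)) == 1  # closed boundary
        assert query_slice_segments(tree, 1.3) == []

    def test_stabbing_matches_linear_scan(self, rng):
        lines = _random_lines(rng, n_lines=40, n_pts=6)
        tree = build_interval_tree(lines)
        for z in rng.uniform(-2, 22, size=50):
            got = query_slice_segments(tree, z)
            expected = [tree.segments[i] for i in _stab_oracle(tree, z)]
            assert got == expected

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            build_interval_tree(ColoredPolylineSet([]))


def _oracle_voxelize(lines, grid):
    """Exhaustive per-voxel distance + nearest-vertex oracle (circle tubes)."""
    xs = grid.voxel_centers_1d(0)
    ys = grid.voxel_centers_1d(1)
    zs = grid.voxel_centers_1d(2)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    centers = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    solid = np.zeros(len(centers), dtype=bool)
    for line in lines:
        r = line.radius
        for i in range(len(line.vertices) - 1):
            a, b = line.vertices[i], line.vertices[i + 1]
            ab = b - a
            t = np.clip((centers - a) @ ab / (ab @ ab), 0, 1)
            d = np.linalg.norm(centers - (a + t[:, None] * ab), axis=1)
            solid |= d <= r + 1e-12
    # nearest-vertex colors with lowest-index tie-break
    order = sorted(lines.polylines, key=lambda p: p.id)
    verts = np.concatenate([p.vertices for p in order])
    cols = np.concatenate([p.vertex_colors for p in order])
    colors = np.zeros((len(centers), 3))
    for n in np.nonzero(solid)[0]:
        d = np.linalg.norm(verts - centers[n], axis=1)
        nearest = np.nonzero(d <= d.min() + 1e-9)[0][0]  # lowest-index tie-break
        colors[n] = cols[nearest]
    return solid.reshape(grid.dims), colors.reshape(grid.dims + (3,))


class TestVoxelizePolylines:
    def test_axis_aligned_segment_fills_exact_voxel_column(self):
        grid = GridSpec((5, 5, 8))
        # through the centers of column (2, 2, :), radius = half in-plane spacing
        line = Polyline(
            0,
            [(2.5, 2.5, 0.5), (2.5, 2.5, 7.5)],
            [(1, 0, 0), (0, 0, 1)],
            thickness=1.0,
        )
        out = voxelize_polylines(ColoredPolylineSet([line]), grid)
        expected = np.zeros((5, 5, 8), dtype=bool)
        expected[2, 2, :] = True
        assert np.array_equal(out.geometry, expected)
        # each voxel takes the color of its nearest endpoint
        assert np.allclose(out.color[2, 2, 0], (1, 0, 0))
        assert np.allclose(out.color[2, 2, 7], (0, 0, 1))

    def test_matches_exhaustive_oracle_on_random_polyline(self, rng):
        grid = GridSpec((32, 32, 32))
        verts = rng.uniform(4, 28, size=(5, 3))
        line = Polyline(0, verts, rng.random((5, 3)), thickness=3.0)
        lines = ColoredPolylineSet([line])
        out = voxelize_polylines(lines, grid)
        solid, colors = _oracle_voxelize(lines, grid)
        assert np.array_equal(out.geometry, solid)
        assert np.allclose(out.color[solid], colors[solid])

    def test_voxelization_monotone_in_radius(self, rng):
        grid = GridSpec((24, 24, 24))
        verts = rng.uniform(5, 19, size=(4, 3))
        cols = rng.random((4, 3))
        small = voxelize_polylines(
            ColoredPolylineSet([Polyline(0, verts, cols, 1.0)]), grid
        )
        big = voxelize_polylines(
            ColoredPolylineSet([Polyline(0, verts, cols, 3.0)]), grid
        )
        assert not (small.geometry & ~big.geometry).any()

    def test_solid_centers_within_radius_plus_half_diagonal(self, rng):
        grid = GridSpec((20, 20, 20))
        verts = rng.uniform(4, 16, size=(4, 3))
        line = Polyline(0, verts, rng.random((4, 3)), thickness=2.0)
        out = voxelize_polylines(ColoredPolylineSet([line]), grid)
        bound = line.radius + 0.5 * np.sqrt(3)
        ii, jj, kk = np.nonzero(out.geometry)
        centers = np.stack(
            [grid.voxel_centers_1d(0)[ii], grid.voxel_centers_1d(1)[jj],
             grid.voxel_centers_1d(2)[kk]], axis=1
        )
        for c in centers:
            dmin = np.inf
            for i in range(len(verts) - 1):
                a, b = verts[i], verts[i + 1]
                ab = b - a
                t = np.clip((c - a) @ ab / (ab @ ab), 0, 1)
                dmin = min(dmin, float(np.linalg.norm(c - (a + t * ab))))
            assert dmin <= bound + 1e-9

    def test_color_assignment_invariant_to_polyline_order(self, rng):
        grid = GridSpec((20, 20, 20))
        l0 = Polyline(0, rng.uniform(4, 16, (3, 3)), rng.random((3, 3)), 2.0)
        l1 = Polyline(1, rng.uniform(4, 16, (3, 3)), rng.random((3, 3)), 2.0)
        a = voxelize_polylines(ColoredPolylineSet([l0, l1]), grid)
        b = voxelize_polylines(ColoredPolylineSet([l1, l0]), grid)
        assert np.array_equal(a.geometry, b.geometry)
        assert np.allclose(a.color, b.color)

    @pytest.mark.parametrize("shape", ["square", "triangle"])
    def test_noncircular_sections_bounded_by_circumcircle(self, rng, shape):
        grid = GridSpec((20, 20, 20))
        verts = rng.uniform(5, 15, (3, 3))
        cols = rng.random((3, 3))
        prof = voxelize_polylines(
            ColoredPolylineSet([Polyline(0, verts, cols, 2.0, shape)]), grid
        )
        disc = voxelize_polylines(
            ColoredPolylineSet([Polyline(0, verts, cols, 2.0, "circle")]), grid
        )
        assert not (prof.geometry & ~disc.geometry).any()

    def test_too_small_grid_reports_required_bounds(self):
        line = Polyline(0, [(0, 0, 0), (30, 0, 0)], [(1, 0, 0)] * 2, 1.0)
        with pytest.raises(ValueError, match="need world bounds"):
            voxelize_polylines(ColoredPolylineSet([line]), GridSpec((4, 4, 4)))


def _cube_mesh(color=(1.0, 0.0, 0.0), size=4.0, center=(5.0, 5.0, 5.0)):
    h = size / 2
    c = np.asarray(center)
    verts = c + np.array(
        [[sx, sy, sz] for sx in (-h, h) for sy in (-h, h) for sz in (-h, h)]
    )
    faces = np.array(
        [
            (0, 1, 3), (0, 3, 2), (4, 6, 7), (4, 7, 5),
            (0, 4, 5), (0, 5, 1), (2, 3, 7), (2, 7, 6),
            (0, 2, 6), (0, 6, 4), (1, 5, 7), (1, 7, 3),
        ]
    )
    return ColoredMesh(verts, np.tile(color, (8, 1)), faces)


class TestVoxelizeColoredMesh:
    def test_red_cube_fills_interior_red(self):
        grid = GridSpec((10, 10, 10))
        out = voxelize_colored_mesh(_cube_mesh(), grid)
        # cube spans [3, 7]^3: interior voxel centers 3.5..6.5 -> 4^3 voxels
        assert out.solid_count == 64
        assert np.allclose(out.color[out.geometry], (1.0, 0.0, 0.0))

    def test_icosphere_volume_within_five_percent_of_analytic(self):
        import trimesh

        R = 5.0
        m = trimesh.creation.icosphere(subdivisions=3, radius=R)
        mesh = ColoredMesh(m.vertices + 6.0, np.ones((len(m.vertices), 3)), m.faces)
        grid = GridSpec((60, 60, 60), (0.2, 0.2, 0.2))
        out = voxelize_colored_mesh(mesh, grid)
        vox_volume = out.solid_count * 0.2**3
        assert vox_volume == pytest.approx(4 / 3 * np.pi * R**3, rel=0.05)

    def test_two_tone_sphere_matches_nearest_vertex_oracle(self):
        import trimesh

        m = trimesh.creation.icosphere(subdivisions=2, radius=4.0)
        colors = np.where(m.vertices[:, 0:1] >= 0, (1.0, 0.0, 0.0), (0.0, 0.0, 1.0))
        mesh = ColoredMesh(m.vertices + 5.0, colors, m.faces)
        grid = GridSpec((10, 10, 10))
        out = voxelize_colored_mesh(mesh, grid)
        ii, jj, kk = np.nonzero(out.geometry)
        for i, j, k in zip(ii, jj, kk):
            c = np.array([i + 0.5, j + 0.5, k + 0.5])
            d = np.linalg.norm(mesh.vertices - c, axis=1)
            nearest = np.nonzero(d <= d.min() + 1e-9)[0][0]
            assert np.allclose(out.color[i, j, k], mesh.colors[nearest])

    def test_open_mesh_rejected_with_edge_count(self):
        mesh = _cube_mesh()
        broken = ColoredMesh(mesh.vertices, mesh.colors, mesh.faces[:-1])
        with pytest.raises(ValueError, match="3 open"):
            voxelize_colored_mesh(broken, GridSpec((10, 10, 10)))
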