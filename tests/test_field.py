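"""Voxel-field construction, overlay compositing and clear-hull tests."""

from collections import deque

import numpy as np
import pytest

from voxelprint import (
    ColorLUT,
    GridSpec,
    MultiChannelVoxelField,
    OverlayLayer,
    OverlayStack,
    ScalarVolume,
    from_scalar_volume,
    make_clear_hull,
    overlay_fields,
)
from conftest import random_field, uniform_field


def _volume(intensities, spacing=(1, 1, 1)):
    arr = np.asarray(intensities, dtype=float)
    return ScalarVolume(GridSpec(arr.shape, spacing), arr)


def _flood_fill_largest(solid):
    """Independent largest-26-connected-component oracle (BFS)."""
    solid = np.asarray(solid, bool)
    seen = np.zeros_like(solid)
    best = set()
    dims = solid.shape
    for start in zip(*np.nonzero(solid)):
        if seen[start]:
            continue
        comp = []
        q = deque([start])
        seen[start] = True
        while q:
            i, j, k = q.popleft()
            comp.append((i, j, k))
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        if di == dj == dk == 0:
                            continue
                        ni, nj, nk = i + di, j + dj, k + dk
                        if (
                            0 <= ni < dims[0]
                            and 0 <= nj < dims[1]
                            and 0 <= nk < dims[2]
                            and solid[ni, nj, nk]
                            and not seen[ni, nj, nk]
                        ):
                            seen[ni, nj, nk] = True
                            q.append((ni, nj, nk))
        if len(comp) > len(best):
            best = set(comp)
    return best


class TestFromScalarVolume:
    def test_all_zero_volume_yields_void_field_with_warning(self, gray_lut):
        vol = _volume(np.zeros((4, 4, 4)))
        with pytest.warns(UserWarning, match="empty solid set"):
            field = from_scalar_volume(vol, 0.1, 1.0, gray_lut)
        assert field.solid_count == 0

    def test_single_voxel_in_band(self, gray_lut):
        data = np.zeros((5, 5, 5))
        data[2, 3, 1] = 0.5
        field = from_scalar_volume(_volume(data), 0.4, 0.6, gray_lut)
        assert field.solid_count == 1
        assert field.geometry[2, 3, 1]

    def test_band_is_inclusive_at_both_ends(self, gray_lut):
        data = np.zeros((3, 1, 1))
        data[0] = 0.4
        data[1] = 0.6
        data[2] = 0.61
        field = from_scalar_volume(_volume(data), 0.4, 0.6, gray_lut)
        assert list(field.geometry[:, 0, 0]) == [True, True, False]

    def test_solid_count_matches_bruteforce_scan(self, rng, gray_lut):
        data = rng.random((32, 32, 32))
        field = from_scalar_volume(_volume(data), 0.4, 0.6, gray_lut)
        expected = sum(
            1 for v in data.ravel() if 0.4 <= v <= 0.6
        )  # per-voxel scan oracle
        assert field.solid_count == expected

    def test_largest_component_matches_flood_fill_oracle(self, rng, gray_lut):
        data = rng.random((16, 16, 16))
        field = from_scalar_volume(
            _volume(data), 0.55, 1.0, gray_lut, keep_largest_component=True
        )
        oracle = _flood_fill_largest((data >= 0.55) & (data <= 1.0))
        assert set(zip(*np.nonzero(field.geometry))) == oracle

    def test_solid_count_monotone_in_lower_threshold(self, rng, gray_lut):
        data = rng.random((12, 12, 12))
        counts = [
            from_scalar_volume(_volume(data), lo, 0.9, gray_lut).solid_count
            for lo in (0.1, 0.3, 0.5, 0.7)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_colors_come_from_lut_and_clear_from_opacity(self, gray_lut):
        data = np.full((2, 2, 2), 0.75)
        field = from_scalar_volume(_volume(data), 0.0, 1.0, gray_lut)
        assert np.allclose(field.color[field.geometry], 0.75)
        # alpha 0.75 with the default 70-95% band, gamma 1
        assert np.allclose(field.clear_fraction[field.geometry], 0.95 - 0.25 * 0.75)

    def test_mismatched_lut_domain_is_an_error(self):
        lut = ColorLUT.from_points(
            [(0.2, (0, 0, 0), 0.0), (0.8, (1, 1, 1), 1.0)]
        )
        with pytest.raises(ValueError, match="LUT domain"):
            from_scalar_volume(_volume(np.full((2, 2, 2), 0.9)), 0.0, 1.0, lut)


class TestOverlayFields:
    def test_void_overlay_leaves_base_unchanged(self, rng):
        base = random_field(rng)
        void = MultiChannelVoxelField.empty(base.grid)
        out = overlay_fields(OverlayStack.of(base, void))
        assert np.array_equal(out.geometry, base.geometry)
        assert np.allclose(out.color, np.where(base.geometry[..., None], base.color, 0))
        assert np.allclose(
            out.clear_fraction, np.where(base.geometry, base.clear_fraction, 0)
        )

    def test_everywhere_solid_overlay_paints_every_voxel(self, rng):
        base = random_field(rng)
        orange = uniform_field(base.grid.dims, color=(1.0, 0.5, 0.0))
        out = overlay_fields(OverlayStack.of(base, (orange, "color-only")))
        assert np.allclose(out.color[out.geometry], (1.0, 0.5, 0.0))
        # color-only: geometry unchanged
        assert np.array_equal(out.geometry, base.geometry)

    def test_three_layers_match_last_wins_scan_oracle(self, rng):
        dims = (6, 6, 6)
        base = random_field(rng, dims, 0.6)
        l1 = random_field(rng, dims, 0.4)
        l2 = random_field(rng, dims, 0.4)
        modes = ("color-and-geometry", "color-only")
        out = overlay_fields(OverlayStack.of(base, (l1, modes[0]), (l2, modes[1])))

        layers = [(base, "color-and-geometry"), (l1, modes[0]), (l2, modes[1])]
        for idx in np.ndindex(dims):
            solid = any(
                f.geometry[idx] for f, m in layers if m == "color-and-geometry"
            )
            assert out.geometry[idx] == solid
            if not solid:
                continue
            winner = None
            for f, _m in layers:  # last solid layer wins the color
                if f.geometry[idx]:
                    winner = f
            assert winner is not None
            assert np.allclose(out.color[idx], winner.color[idx])
            assert out.clear_fraction[idx] == winner.clear_fraction[idx]

    def test_idempotent_for_single_layer_and_self_overlay(self, rng):
        base = random_field(rng)
        once = overlay_fields(OverlayStack.of(base))
        twice = overlay_fields(OverlayStack.of(base, (base, "color-and-geometry")))
        for a, b in ((once, twice),):
            assert np.array_equal(a.geometry, b.geometry)
            assert np.allclose(a.color, b.color)

    def test_no_color_on_void_and_union_geometry(self, rng):
        base = random_field(rng, solid_p=0.3)
        ov = random_field(rng, solid_p=0.3)
        out = overlay_fields(OverlayStack.of(base, (ov, "color-and-geometry")))
        assert out.solid_count >= base.solid_count
        assert np.allclose(out.color[~out.geometry], 0.0)

    def test_grid_mismatch_is_an_error(self, rng):
        base = random_field(rng, (4, 4, 4))
        other = random_field(rng, (5, 4, 4))
        with pytest.raises(ValueError, match="grid mismatch"):
            OverlayStack.of(base, other)


class TestClearHull:
    def test_single_voxel_grows_its_26_neighborhood(self):
        field = MultiChannelVoxelField.empty(GridSpec((7, 7, 7)))
        field.geometry[3, 3, 3] = True
        field.color[3, 3, 3] = (0.2, 0.4, 0.6)
        out = make_clear_hull(field, 1)
        assert out.solid_count == 27
        assert np.allclose(out.color[3, 3, 3], (0.2, 0.4, 0.6))  # center untouched
        hull = out.geometry & ~field.geometry
        assert hull.sum() == 26
        assert np.allclose(out.clear_fraction[hull], 1.0)

    @pytest.mark.parametrize("k", [1, 2])
    def test_hull_equals_bruteforce_dilation_minus_solid(self, rng, k):
        field = random_field(rng, (12, 12, 12), solid_p=0.05)
        # keep the solid away from the boundary so the shell fits
        field.geometry[:3] = field.geometry[-3:] = False
        field.geometry[:, :3] = field.geometry[:, -3:] = False
        field.geometry[:, :, :3] = field.geometry[:, :, -3:] = False
        if not field.geometry.any():
            field.geometry[6, 6, 6] = True
        out = make_clear_hull(field, k)
        dil = np.zeros_like(field.geometry)
        for i, j, l in zip(*np.nonzero(field.geometry)):  # exhaustive dilation
            dil[
                max(i - k, 0) : i + k + 1,
                max(j - k, 0) : j + k + 1,
                max(l - k, 0) : l + k + 1,
            ] = True
        expected_hull = dil & ~field.geometry
        assert np.array_equal(out.geometry & ~field.geometry, expected_hull)

    def test_hull_disjoint_and_boundary_voxels_have_hull_neighbors(self, rng):
        field = random_field(rng, (10, 10, 10), solid_p=0.08)
        field.geometry[:2] = field.geometry[-2:] = False
        field.geometry[:, :2] = field.geometry[:, -2:] = False
        field.geometry[:, :, :2] = field.geometry[:, :, -2:] = False
        if not field.geometry.any():
            field.geometry[5, 5, 5] = True
        out = make_clear_hull(field, 1)
        hull = out.geometry & ~field.geometry
        assert not (hull & field.geometry).any()
        for i, j, k in zip(*np.nonzero(field.geometry)):
            nb = out.geometry[
                max(i - 1, 0) : i + 2, max(j - 1, 0) : j + 2, max(k - 1, 0) : k + 2
            ]
            solid_nb = field.geometry[
                max(i - 1, 0) : i + 2, max(j - 1, 0) : j + 2, max(k - 1, 0) : k + 2
            ]
            boundary = not solid_nb.all()
            if boundary:
                assert (nb & ~solid_nb).any()

    def test_empty_field_warns_and_returns_unchanged(self):
        field = MultiChannelVoxelField.empty(GridSpec((4, 4, 4)))
        with pytest.warns(UserWarning, match="nothing to enclose"):
            out = make_clear_hull(field, 1)
        assert out.solid_count == 0

    def test_shell_exceeding_grid_advises_padding(self):
        field = MultiChannelVoxelField.empty(GridSpec((4, 4, 4)))
        field.geometry[0, 0, 0] = True
        with pytest.raises(ValueError, match="pad the grid"):
            make_clear_hull(field, 1)
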