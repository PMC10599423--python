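"""Transfer-function tests: windowing, LUTs, opacity compensation, DEC colors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from voxelprint import (
    ColorLUT,
    GridSpec,
    OpacityCurve,
    ScalarVolume,
    apply_lut,
    compensate_transparency,
    orientation_to_rgb,
    window_level,
)


def _volume(arr):
    arr = np.asarray(arr, float)
    return ScalarVolume(GridSpec(arr.shape), arr)


class TestWindowLevel:
    def test_full_range_window_at_midpoint_is_identity(self, rng):
        vol = _volume(rng.random((6, 6, 6)))
        out = window_level(vol, window=1.0, level=0.5)
        assert np.allclose(out.intensities, vol.intensities)

    def test_intensity_at_level_maps_to_half(self):
        vol = _volume(np.full((2, 2, 2), 0.3))
        out = window_level(vol, window=0.4, level=0.3)
        assert np.allclose(out.intensities, 0.5)

    def test_matches_closed_form_clamp_formula(self, rng):
        data = rng.random((16, 16, 16))
        out = window_level(_volume(data), window=0.4, level=0.3)
        expected = np.clip((data - (0.3 - 0.2)) / 0.4, 0.0, 1.0)
        assert np.allclose(out.intensities, expected)

    def test_monotone_nondecreasing(self, rng):
        data = np.sort(rng.random(100)).reshape(100, 1, 1)
        out = window_level(_volume(data), window=0.25, level=0.6)
        assert np.all(np.diff(out.intensities[:, 0, 0]) >= 0)

    def test_composition_equals_equivalent_single_window(self, rng):
        # windows whose supports stay inside [0, 1] compose to one window
        data = rng.random((8, 8, 8))
        w1, l1 = 0.8, 0.5
        w2, l2 = 0.6, 0.5
        twice = window_level(window_level(_volume(data), w1, l1), w2, l2)
        # x -> ((x - a1)/w1 - a2)/w2 with a = level - window/2
        a1, a2 = l1 - w1 / 2, l2 - w2 / 2
        combined = np.clip(((data - a1) / w1 - a2) / w2, 0.0, 1.0)
        assert np.allclose(twice.intensities, combined, atol=1e-12)

    def test_degenerate_percentile_pair_is_an_error(self, rng):
        vol = _volume(rng.random((4, 4, 4)))
        with pytest.raises(ValueError, match="percentile"):
            window_level(vol, 0.5, 0.5, clip_percentiles=(99.0, 1.0))

    def test_percentile_clipping_applies_before_window(self, rng):
        data = rng.random((16, 16, 16))
        out = window_level(_volume(data), 1.0, 0.5, clip_percentiles=(10.0, 90.0))
        plo, phi = np.percentile(data, [10.0, 90.0])
        expected = np.clip(np.clip(data, plo, phi), 0.0, 1.0)
        assert np.allclose(out.intensities, expected)


class TestColorLUT:
    lut = ColorLUT.from_points(
        [
            (0.2, (1.0, 0.0, 0.0), 0.1),
            (0.6, (0.0, 1.0, 0.0), 0.5),
            (0.9, (0.0, 0.0, 1.0), 0.9),
        ]
    )

    def test_exact_at_control_points(self):
        rgb, alpha = self.lut(np.array([0.2, 0.6, 0.9]))
        assert np.allclose(rgb, [(1, 0, 0), (0, 1, 0), (0, 0, 1)])
        assert np.allclose(alpha, [0.1, 0.5, 0.9])

    def test_midpoint_is_channelwise_average(self):
        rgb, alpha = self.lut(0.4)
        assert np.allclose(rgb, (0.5, 0.5, 0.0))
        assert np.isclose(alpha, 0.3)

    def test_clamped_outside_domain(self):
        rgb_lo, _ = self.lut(0.0)
        rgb_hi, _ = self.lut(1.0)
        assert np.allclose(rgb_lo, (1, 0, 0))
        assert np.allclose(rgb_hi, (0, 0, 1))

    def test_output_inside_convex_hull_of_control_colors(self, rng):
        x = rng.random(500)
        rgb, _ = self.lut(x)
        # control colors are the RGB simplex corners: hull = componentwise
        # range plus unit sum bound
        assert rgb.min() >= -1e-12 and rgb.max() <= 1 + 1e-12
        assert np.all(rgb.sum(axis=1) <= 1 + 1e-9)

    def test_apply_lut_evaluates_over_volume(self, rng):
        vol = _volume(rng.random((4, 4, 4)))
        rgb, alpha = apply_lut(vol, self.lut)
        assert rgb.shape == (4, 4, 4, 3)
        assert alpha.shape == (4, 4, 4)

    def test_rejects_nonincreasing_control_points(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ColorLUT.from_points(
                [(0.5, (0, 0, 0), 0.0), (0.5, (1, 1, 1), 1.0)]
            )


class TestCompensateTransparency:
    def test_band_endpoints_with_defaults(self):
        assert compensate_transparency(0.0) == pytest.approx(0.95)
        assert compensate_transparency(1.0) == pytest.approx(0.70)

    def test_midpoint_closed_form(self):
        assert compensate_transparency(0.5, OpacityCurve(gamma=1.0)) == pytest.approx(
            0.825
        )

    @pytest.mark.parametrize("gamma", [0.3, 1.0, 2.7])
    def test_strictly_decreasing_and_band_bounded(self, gamma):
        curve = OpacityCurve(gamma=gamma)
        a = np.linspace(0, 1, 201)
        cf = compensate_transparency(a, curve)
        assert np.all(np.diff(cf) < 0)
        assert cf.min() >= curve.clear_min and cf.max() <= curve.clear_max

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            OpacityCurve(clear_min=0.9, clear_max=0.8)


class TestOrientationToRGB:
    def test_axis_endpoint_convention(self):
        assert np.allclose(orientation_to_rgb((1, 0, 0)), (1, 0, 0))

    def test_antipodal_symmetry(self):
        assert np.allclose(orientation_to_rgb((0, 0, -1)), (0, 0, 1))

    def test_diagonal_direction(self):
        v = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        assert np.allclose(orientation_to_rgb(v), [0.57735] * 3, atol=1e-5)

    def test_zero_vector_is_an_error(self):
        with pytest.raises(ValueError, match="zero vector"):
            orientation_to_rgb((0.0, 0.0, 0.0))

    @settings(deadline=None, derandomize=True)
    @given(
        st.tuples(*[st.floats(-10, 10) for _ in range(3)]).filter(
            lambda v: sum(x * x for x in v) > 1e-6
        ),
        st.floats(0.01, 50.0),
    )
    def test_invariant_under_negation_and_scaling(self, v, s):
        base = orientation_to_rgb(v)
        assert np.allclose(orientation_to_rgb([-x for x in v]), base, atol=1e-9)
        assert np.allclose(orientation_to_rgb([s * x for x in v]), base, atol=1e-9)
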