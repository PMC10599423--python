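import numpy as np
import pytest

from voxelprint import GridSpec, MultiChannelVoxelField


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def uniform_field(
    dims=(16, 16, 16),
    color=(0.5, 0.5, 0.5),
    clear=0.0,
    spacing=(1.0, 1.0, 1.0),
) -> MultiChannelVoxelField:
    """Fully solid field with one uniform (RGB, clear) mix everywhere."""
    grid = GridSpec(dims, spacing)
    return MultiChannelVoxelField(
        grid,
        np.ones(dims, dtype=bool),
        np.broadcast_to(np.asarray(color, float), dims + (3,)).copy(),
        np.full(dims, float(clear)),
    )


def random_field(rng, dims=(8, 8, 8), solid_p=0.5) -> MultiChannelVoxelField:
    """Seeded field with random occupancy, colors and clear fractions."""
    grid = GridSpec(dims)
    solid = rng.random(dims) < solid_p
    color = np.where(solid[..., None], rng.random(dims + (3,)), 0.0)
    clear = np.where(solid, rng.random(dims), 0.0)
    return MultiChannelVoxelField(grid, solid, color, clear)


@pytest.fixture
def gray_lut():
    from voxelprint import ColorLUT

    return ColorLUT.from_points(
        [(0.0, (0.0, 0.0, 0.0), 0.0), (1.0, (1.0, 1.0, 1.0), 1.0)]
    )
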