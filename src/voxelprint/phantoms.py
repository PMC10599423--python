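"""Seeded synthetic phantoms for every input class of the pipeline.

Patient imaging data cannot ship with the package, so each input modality is
emulated by a generator that imitates its statistical structure — intensity
bands for T1-like anatomy, Gaussian hotspots for activation maps, colored
helical bundles for flow streamlines, and a full-gamut color block for
dither testing.  No claim of anatomical or physiological realism is made.
Every generator is a pure function of its spec: a fixed seed yields
byte-identical output, and no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .field import MultiChannelVoxelField
from .grid import GridSpec
from .tracts import PT_TO_MM, ColoredPolylineSet, Polyline
from .transfer import ColorLUT

__all__ = [
    "BrainPhantomSpec",
    "ActivationPhantomSpec",
    "FlowPhantomSpec",
    "GamutPhantomSpec",
    "velocity_lut",
    "make_brain_phantom",
    "make_activation_overlay",
    "make_flow_streamlines",
    "make_gamut_block",
]

# intensity bands of the T1-like phantom (normalized units)
GRAY_BAND = 0.50
WHITE_BAND = 0.80
LESION_BAND = 0.95


def _grid(dims, spacing, origin=(0.0, 0.0, 0.0)) -> GridSpec:
    return GridSpec(tuple(dims), tuple(spacing), tuple(origin))


def _centers(grid: GridSpec):
    return np.meshgrid(
        grid.voxel_centers_1d(0),
        grid.voxel_centers_1d(1),
        grid.voxel_centers_1d(2),
        indexing="ij",
    )


@dataclass(frozen=True)
class BrainPhantomSpec:
    """T1-like masked brain phantom: nested smoothed ellipsoidal bands.

    Background ~0, an outer "gray-matter" shell at ``GRAY_BAND``, an inner
    "white-matter" ellipsoid at ``WHITE_BAND`` and an optional "lesion" blob
    at ``LESION_BAND``.  The default grid matches a 170-slice, 1 mm
    isotropic T1 acquisition.
    """

    seed: int = 0
    dims: tuple[int, int, int] = (128, 128, 170)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    outer_semiaxes_mm: tuple[float, float, float] = (45.0, 52.0, 70.0)
    inner_semiaxes_mm: tuple[float, float, float] = (28.0, 33.0, 46.0)
    lesion_center_offset_mm: tuple[float, float, float] = (14.0, 9.0, 18.0)
    lesion_radius_mm: float = 8.0
    include_lesion: bool = True
    noise_amplitude: float = 0.02
    smooth_sigma_mm: float = 0.8


def make_brain_phantom(spec: BrainPhantomSpec = BrainPhantomSpec()):
    """Generate the T1-like scalar volume described by ``spec``."""
    from .volume import ScalarVolume

    grid = _grid(spec.dims, spec.spacing)
    center = 0.5 * np.asarray(grid.extent)
    for axes in (spec.outer_semiaxes_mm, spec.inner_semiaxes_mm):
        if any(a >= c for a, c in zip(axes, center)):
            raise ValueError(
                f"ellipsoid semi-axes {axes} exceed the half-extent {tuple(center)}"
            )
    gx, gy, gz = _centers(grid)

    def ellipsoid(c, semiaxes):
        return (
            ((gx - c[0]) / semiaxes[0]) ** 2
            + ((gy - c[1]) / semiaxes[1]) ** 2
            + ((gz - c[2]) / semiaxes[2]) ** 2
        ) <= 1.0

    outer = ellipsoid(center, spec.outer_semiaxes_mm)
    inner = ellipsoid(center, spec.inner_semiaxes_mm)
    x = np.zeros(grid.dims)
    x[outer] = GRAY_BAND
    x[inner] = WHITE_BAND
    if spec.include_lesion:
        lc = center + np.asarray(spec.lesion_center_offset_mm)
        r = spec.lesion_radius_mm
        lesion = ellipsoid(lc, (r, r, r))
        x[lesion] = LESION_BAND

    rng = np.random.default_rng(spec.seed)
    sigma_vox = [spec.smooth_sigma_mm / s for s in grid.spacing]
    x = ndimage.gaussian_filter(x, sigma=sigma_vox)
    x = x + spec.noise_amplitude * rng.standard_normal(grid.dims) * (x > 0.05)
    return ScalarVolume(grid, np.clip(x, 0.0, 1.0), 16)


@dataclass(frozen=True)
class ActivationPhantomSpec:
    """fMRI-like overlay: a sum of anisotropic Gaussian hotspots plus noise.

    ``hotspots`` is a tuple of (center_mm, sigmas_mm, amplitude); seeded
    uniform background noise in [0, noise_amplitude] emulates imaging noise
    that thresholding must eliminate.
    """

    seed: int = 0
    dims: tuple[int, int, int] = (128, 128, 170)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    hotspots: tuple = (
        ((44.0, 52.0, 102.0), (6.0, 8.0, 5.0), 1.0),
        ((80.0, 70.0, 76.0), (5.0, 5.0, 7.0), 0.6),
    )
    noise_amplitude: float = 0.05


def gaussian_hotspot_field(spec: ActivationPhantomSpec) -> np.ndarray:
    """Closed-form noiseless hotspot field (also the test oracle's formula)."""
    grid = _grid(spec.dims, spec.spacing)
    gx, gy, gz = _centers(grid)
    x = np.zeros(grid.dims)
    for center, sigmas, amp in spec.hotspots:
        x += amp * np.exp(
            -0.5
            * (
                ((gx - center[0]) / sigmas[0]) ** 2
                + ((gy - center[1]) / sigmas[1]) ** 2
                + ((gz - center[2]) / sigmas[2]) ** 2
            )
        )
    return x


def make_activation_overlay(spec: ActivationPhantomSpec = ActivationPhantomSpec()):
    """Generate the fMRI-like scalar volume described by ``spec``."""
    from .volume import ScalarVolume

    grid = _grid(spec.dims, spec.spacing)
    x = gaussian_hotspot_field(spec)
    rng = np.random.default_rng(spec.seed)
    x = x + rng.uniform(0.0, spec.noise_amplitude, grid.dims)
    return ScalarVolume(grid, np.clip(x, 0.0, 1.0), 8)


def velocity_lut() -> ColorLUT:
    """Blue-to-red speed colormap conventional for flow streamlines."""
    return ColorLUT.from_points(
        [
            (0.0, (0.0, 0.0, 1.0), 1.0),
            (0.25, (0.0, 1.0, 1.0), 1.0),
            (0.5, (0.0, 1.0, 0.0), 1.0),
            (0.75, (1.0, 1.0, 0.0), 1.0),
            (1.0, (1.0, 0.0, 0.0), 1.0),
        ]
    )


@dataclass(frozen=True)
class FlowPhantomSpec:
    """Velocity-colored helical streamline bundle.

    ``n_lines`` helical arcs wind inside a cube of ``extent_mm``; per-vertex
    speed varies along each arc, peaks exactly at ``max_speed_mm_s`` over
    the set, and is mapped through :func:`velocity_lut` to RGB.
    """

    seed: int = 0
    n_lines: int = 25
    points_per_line: int = 40
    extent_mm: float = 40.0
    max_speed_mm_s: float = 1000.0
    thickness_pt: float = 1.0
    cross_section: str = "circle"


def make_flow_streamlines(spec: FlowPhantomSpec = FlowPhantomSpec()) -> ColoredPolylineSet:
    """Generate the streamline bundle described by ``spec``."""
    if spec.n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = np.random.default_rng(spec.seed)
    lut = velocity_lut()
    half = spec.extent_mm / 2.0
    c0 = np.array([half, half, half])
    polylines = []
    speeds_all = []
    verts_all = []
    for i in range(spec.n_lines):
        # helical arc: random radius, pitch, phase, axis offset
        radius = rng.uniform(0.25, 0.7) * half * 0.8
        pitch = rng.uniform(0.3, 0.9) * half
        phase = rng.uniform(0, 2 * np.pi)
        turns = rng.uniform(0.75, 1.5)
        off = rng.uniform(-0.15, 0.15, size=3) * half
        t = np.linspace(0.0, 1.0, spec.points_per_line)
        ang = phase + turns * 2 * np.pi * t
        verts = np.stack(
            [
                c0[0] + off[0] + radius * np.cos(ang),
                c0[1] + off[1] + radius * np.sin(ang),
                c0[2] + off[2] + pitch * (t - 0.5),
            ],
            axis=1,
        )
        # speed profile along the arc (peaks mid-arc)
        base = rng.uniform(0.3, 0.9)
        profile = base * (0.4 + 0.6 * np.sin(np.pi * t) ** 2)
        verts_all.append(verts)
        speeds_all.append(profile)

    peak = max(float(s.max()) for s in speeds_all)
    for i, (verts, profile) in enumerate(zip(verts_all, speeds_all)):
        speed = profile / peak * spec.max_speed_mm_s
        rgb, _ = lut(speed / spec.max_speed_mm_s)
        polylines.append(
            Polyline(
                id=i,
                vertices=verts,
                vertex_colors=rgb,
                thickness=spec.thickness_pt * PT_TO_MM,
                cross_section=spec.cross_section,
            )
        )
    return ColoredPolylineSet(polylines)


@dataclass(frozen=True)
class GamutPhantomSpec:
    """Full-gamut color/clear test block (all voxels solid)."""

    seed: int = 0
    dims: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (0.1, 0.1, 0.03)


# the six (R, G, B, clear) mixing targets of the default palette
_PALETTE_TARGETS = (
    (0.0, 1.0, 1.0, 0.0),  # cyan
    (1.0, 0.0, 1.0, 0.0),  # magenta
    (1.0, 1.0, 0.0, 0.0),  # yellow
    (0.0, 0.0, 0.0, 0.0),  # black
    (1.0, 1.0, 1.0, 0.0),  # white
    (1.0, 1.0, 1.0, 1.0),  # clear
)


def make_gamut_block(spec: GamutPhantomSpec = GamutPhantomSpec()) -> MultiChannelVoxelField:
    """Generate a fully solid block sampling the unit (RGB, clear) 4-cube.

    Each channel takes an evenly spaced sample of [0, 1], independently
    shuffled per channel (so per-channel histograms are uniform); the first
    six voxels are pinned exactly to the default palette's mixing targets so
    every material has at least one zero-error voxel.
    """
    if min(spec.dims) < 16:
        raise ValueError("gamut block dims must be >= 16 per axis")
    grid = _grid(spec.dims, spec.spacing)
    n = int(np.prod(spec.dims))
    rng = np.random.default_rng(spec.seed)
    chan = np.empty((n, 4))
    base = (np.arange(n) + 0.5) / n
    for c in range(4):
        chan[:, c] = rng.permutation(base)
    chan[: len(_PALETTE_TARGETS)] = np.asarray(_PALETTE_TARGETS)
    chan = chan.reshape(spec.dims + (4,))
    return MultiChannelVoxelField(
        grid,
        np.ones(spec.dims, dtype=bool),
        chan[..., :3],
        chan[..., 3],
    )
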