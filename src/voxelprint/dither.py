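"""Volumetric error-diffusion dithering to a discrete material palette.

A multimaterial polyjet printer deposits one resin per voxel, so the
continuous (RGB, clear-fraction) mix of the composited field must be
quantized to the printable palette while preserving local mean color and
translucency.  Quantization error is diffused serpentine within each layer
with Floyd-Steinberg weights, a fixed fraction of the residual is passed to
the voxel directly above in the next layer (making the dither volumetric),
and a seeded high-pass ("blue-noise") threshold perturbation decorrelates
the structured worm artifacts classic error diffusion produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .field import MultiChannelVoxelField
from .grid import GridSpec

__all__ = [
    "Material",
    "MaterialPalette",
    "MaterialVolume",
    "default_palette",
    "dither_volume",
]

VOID = -1  # assignment value for void voxels


@dataclass(frozen=True)
class Material:
    """One printable resin.

    ``rgba_code`` is the exact 8-bit RGBA pixel value identifying this
    material in slice rasters; ``display_rgb`` ([0, 1]) is the color used
    for mixing distance and previews; ``is_clear`` marks the transparent
    resin, which mixes along the fourth (clear-fraction) coordinate.
    """

    name: str
    rgba_code: tuple[int, int, int, int]
    display_rgb: tuple[float, float, float]
    is_clear: bool = False

    @property
    def mixing_vector(self) -> np.ndarray:
        """(R, G, B, clear) coordinates used for quantization distance."""
        return np.array([*self.display_rgb, 1.0 if self.is_clear else 0.0])


@dataclass(frozen=True)
class MaterialPalette:
    materials: tuple[Material, ...]

    def __post_init__(self) -> None:
        if not self.materials:
            raise ValueError("palette must contain at least one material")
        names = [m.name for m in self.materials]
        codes = [m.rgba_code for m in self.materials]
        if len(set(names)) != len(names):
            raise ValueError("material names must be unique")
        if len(set(codes)) != len(codes):
            raise ValueError("material RGBA codes must be unique")

    def __len__(self) -> int:
        return len(self.materials)

    def __iter__(self):
        return iter(self.materials)

    def __getitem__(self, i: int) -> Material:
        return self.materials[i]

    def index_of(self, name: str) -> int:
        for i, m in enumerate(self.materials):
            if m.name == name:
                return i
        raise KeyError(name)

    def subset(self, names) -> "MaterialPalette":
        """Palette restricted to the named materials, in the given order."""
        return MaterialPalette(
            tuple(self.materials[self.index_of(n)] for n in names)
        )

    @property
    def mixing_vectors(self) -> np.ndarray:
        return np.stack([m.mixing_vector for m in self.materials])

    @property
    def display_rgbs(self) -> np.ndarray:
        return np.stack([np.asarray(m.display_rgb) for m in self.materials])


def default_palette() -> MaterialPalette:
    """The six-resin polyjet palette: CMYK-style colors, white, and clear.

    Mirrors the Vero resin set of a Stratasys J750-class printer (VeroCyan,
    VeroMagenta, VeroYellow, VeroBlackPlus, VeroPureWhite, VeroClear).  The
    RGBA codes are the exact indexed pixel values used in slice rasters;
    clear shares white's RGB but is distinguished by its alpha code.
    """
    return MaterialPalette(
        (
            Material("cyan", (0, 255, 255, 255), (0.0, 1.0, 1.0)),
            Material("magenta", (255, 0, 255, 255), (1.0, 0.0, 1.0)),
            Material("yellow", (255, 255, 0, 255), (1.0, 1.0, 0.0)),
            Material("black", (0, 0, 0, 255), (0.0, 0.0, 0.0)),
            Material("white", (255, 255, 255, 255), (1.0, 1.0, 1.0)),
            Material("clear", (255, 255, 255, 128), (1.0, 1.0, 1.0), is_clear=True),
        )
    )


@dataclass
class MaterialVolume:
    """Per-voxel material assignment after dithering.

    ``assignment`` holds palette indices; ``VOID`` (-1) marks void voxels,
    exactly where the source field was void.
    """

    grid: GridSpec
    palette: MaterialPalette
    assignment: np.ndarray = dc_field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.assignment, dtype=np.int16)
        if arr.shape != self.grid.dims:
            raise ValueError("assignment shape does not match grid dims")
        if arr.size and (arr.min() < VOID or arr.max() >= len(self.palette)):
            raise ValueError("assignment contains invalid material indices")
        self.assignment = arr

    @property
    def solid_count(self) -> int:
        return int((self.assignment != VOID).sum())

    def material_counts(self) -> dict[str, int]:
        return {
            m.name: int((self.assignment == i).sum())
            for i, m in enumerate(self.palette)
        }


def _blue_noise_field(shape, rng: np.random.Generator, sigma: float = 1.5):
    """Zero-mean unit-variance high-pass noise field (per mixing channel).

    White Gaussian noise minus its Gaussian blur concentrates energy at high
    spatial frequencies, the defining property of blue noise.
    """
    white = rng.standard_normal(shape + (4,))
    low = np.stack(
        [ndimage.gaussian_filter(white[..., c], sigma=sigma) for c in range(4)],
        axis=-1,
    )
    high = white - low
    high /= high.std()
    return high


# Floyd-Steinberg in-plane weights, expressed for a left-to-right pass:
# (dx, dy, weight/16): forward 7, below-behind 3, below 5, below-forward 1.
_FS = ((1, 0, 7.0 / 16.0), ((-1), 1, 3.0 / 16.0), (0, 1, 5.0 / 16.0), (1, 1, 1.0 / 16.0))


def dither_volume(
    field: MultiChannelVoxelField,
    palette: MaterialPalette | None = None,
    seed: int = 0,
    kernel: str = "floyd-steinberg",
    interlayer_fraction: float = 0.25,
    blue_noise_amplitude: float = 0.05,
) -> MaterialVolume:
    """Quantize a composited field into per-voxel material assignments.

    The per-voxel target vector is (R, G, B, clear_fraction); materials mix
    in the same 4-space (clear contributes along the fourth coordinate).
    Each solid voxel receives the palette material nearest (Euclidean, ties
    to the lowest palette index) to its error-adjusted, noise-perturbed
    target; the residual error is split ``interlayer_fraction`` to the voxel
    directly above and the remainder through the serpentine in-plane kernel.
    Deterministic for fixed (field, palette, seed).

    ``kernel`` may be ``"floyd-steinberg"`` or ``"none"`` (threshold-only,
    for comparing kernels); ``blue_noise_amplitude`` 0 disables the
    threshold perturbation.
    """
    if palette is None:
        palette = default_palette()
    if not field.geometry.any():
        raise ValueError("cannot dither a field with an empty solid set")
    if not 0.0 <= interlayer_fraction < 1.0:
        raise ValueError("interlayer_fraction must be in [0, 1)")
    if kernel not in ("floyd-steinberg", "none"):
        raise ValueError(f"unknown dither kernel {kernel!r}")

    nx, ny, nz = field.grid.dims
    pal = palette.mixing_vectors  # (M, 4)
    target = np.concatenate(
        [field.color, field.clear_fraction[..., None]], axis=-1
    )  # (nx, ny, nz, 4)
    solid = field.geometry

    rng = np.random.default_rng(seed)
    noise = (
        _blue_noise_field((nx, ny, nz), rng) * blue_noise_amplitude
        if blue_noise_amplitude > 0
        else np.zeros((nx, ny, nz, 4))
    )

    assignment = np.full((nx, ny, nz), VOID, dtype=np.int16)
    diffuse = kernel == "floyd-steinberg"
    f_up = interlayer_fraction
    f_in = 1.0 - f_up

    err_next = np.zeros((nx, ny, nz + 1, 4))  # inter-layer carry, indexed by z+1
    for k in range(nz):
        err = err_next[:, :, k, :].copy()  # in-plane accumulator for layer k
        for j in range(ny):
            rng_lr = (j + k) % 2 == 0  # serpentine: alternate x direction
            xs = range(nx) if rng_lr else range(nx - 1, -1, -1)
            sgn = 1 if rng_lr else -1
            for i in xs:
                if not solid[i, j, k]:
                    continue
                u = target[i, j, k] + err[i, j]
                probe = np.clip(u, 0.0, 1.0) + noise[i, j, k]
                d2 = ((pal - probe) ** 2).sum(axis=1)
                m = int(d2.argmin())
                assignment[i, j, k] = m
                e = np.clip(u - pal[m], -4.0, 4.0)
                if f_up > 0:
                    err_next[i, j, k + 1] += f_up * e
                if diffuse:
                    ein = f_in * e
                    for dx, dy, w in _FS:
                        ii = i + sgn * dx
                        jj = j + dy
                        if 0 <= ii < nx and jj < ny:
                            err[ii, jj] += w * ein
                else:
                    err_next[i, j, k + 1] += f_in * e

    return MaterialVolume(field.grid, palette, assignment)
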