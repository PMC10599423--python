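"""Transfer functions: windowing, color lookup tables, opacity compensation.

Volume-rendering-style transfer functions map normalized image intensity to
color and opacity.  For printing, opacity must additionally be compensated:
perceived translucency of polyjet resins is not linear in the clear-material
mixing ratio, and only the 70-95% clear band gives controlled transparency,
so opacity is mapped into that band by a bounded power curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import ScalarVolume

__all__ = [
    "ColorLUT",
    "OpacityCurve",
    "window_level",
    "apply_lut",
    "compensate_transparency",
    "orientation_to_rgb",
]


@dataclass(frozen=True)
class ColorLUT:
    """Piecewise-linear color/opacity lookup table.

    ``intensities`` are strictly increasing control-point positions in [0, 1];
    ``colors`` are the RGB triples (in [0, 1]) and ``alphas`` the opacities at
    those positions.  Between control points channels interpolate linearly;
    outside the domain the end control points are held (clamp).
    """

    intensities: tuple[float, ...]
    colors: tuple[tuple[float, float, float], ...]
    alphas: tuple[float, ...]

    def __post_init__(self) -> None:
        xs = np.asarray(self.intensities, dtype=float)
        cs = np.asarray(self.colors, dtype=float)
        al = np.asarray(self.alphas, dtype=float)
        if xs.size < 2:
            raise ValueError("a ColorLUT needs at least 2 control points")
        if not np.all(np.diff(xs) > 0):
            raise ValueError("control-point intensities must be strictly increasing")
        if cs.shape != (xs.size, 3):
            raise ValueError("one RGB triple required per control point")
        if al.shape != (xs.size,):
            raise ValueError("one alpha required per control point")
        for arr, name in ((xs, "intensities"), (cs, "colors"), (al, "alphas")):
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_points(cls, points) -> "ColorLUT":
        """Build from an iterable of ``(intensity, (r, g, b), alpha)``."""
        pts = sorted(points, key=lambda p: p[0])
        return cls(
            intensities=tuple(float(p[0]) for p in pts),
            colors=tuple(tuple(float(c) for c in p[1]) for p in pts),
            alphas=tuple(float(p[2]) for p in pts),
        )

    @property
    def domain(self) -> tuple[float, float]:
        return self.intensities[0], self.intensities[-1]

    def __call__(self, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate the LUT: returns (rgb, alpha) arrays.

        ``rgb`` has shape ``intensity.shape + (3,)``.
        """
        x = np.asarray(intensity, dtype=float)
        xs = np.asarray(self.intensities)
        cs = np.asarray(self.colors)
        al = np.asarray(self.alphas)
        rgb = np.stack([np.interp(x, xs, cs[:, ch]) for ch in range(3)], axis=-1)
        alpha = np.interp(x, xs, al)
        return rgb, alpha


# Printable translucency band for polyjet resin mixes: below ~70% clear the
# colored part dominates opaquely; above ~95% translucency becomes erratic.
@dataclass(frozen=True)
class OpacityCurve:
    """Bounded power curve mapping opacity to clear-material fraction.

    clear_fraction(alpha) = clear_max - (clear_max - clear_min) * alpha**gamma

    Fully transparent input (alpha = 0) maps to ``clear_max``; fully opaque
    input (alpha = 1) to ``clear_min``.  Defaults pin the curve to the
    70-95% clear band that gives controlled translucency on polyjet printers.
    """

    clear_min: float = 0.70
    clear_max: float = 0.95
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.clear_min < self.clear_max <= 1.0):
            raise ValueError(
                "need 0 <= clear_min < clear_max <= 1, got "
                f"({self.clear_min}, {self.clear_max})"
            )
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


def window_level(
    volume: ScalarVolume,
    window: float,
    level: float,
    clip_percentiles: tuple[float, float] | None = None,
) -> ScalarVolume:
    """Linear window/level remap of a normalized scalar volume.

    Intensity ``level`` maps to 0.5 and ``level +/- window/2`` to 1 and 0;
    the result is clamped to [0, 1].  When ``clip_percentiles = (lo, hi)`` is
    given (percent), intensities are first clipped to those percentile values
    (histogram processing), before windowing.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    x = volume.intensities
    if clip_percentiles is not None:
        lo, hi = clip_percentiles
        if lo >= hi:
            raise ValueError(f"degenerate percentile pair ({lo}, {hi})")
        plo, phi = np.percentile(x, [lo, hi])
        x = np.clip(x, plo, phi)
    out = np.clip((x - (level - window / 2.0)) / window, 0.0, 1.0)
    return ScalarVolume(volume.grid, out, volume.source_bit_depth)


def apply_lut(volume: ScalarVolume, lut: ColorLUT) -> tuple[np.ndarray, np.ndarray]:
    """Map a scalar volume through a LUT to per-voxel (RGB, alpha) lattices."""
    return lut(volume.intensities)


def compensate_transparency(alpha, curve: OpacityCurve = OpacityCurve()):
    """Convert opacity to clear-material mixing fraction.

    Monotone decreasing in ``alpha`` and bounded to
    ``[curve.clear_min, curve.clear_max]`` for every gamma > 0.  Accepts
    scalars or arrays.
    """
    a = np.clip(np.asarray(alpha, dtype=float), 0.0, 1.0)
    cf = curve.clear_max - (curve.clear_max - curve.clear_min) * a**curve.gamma
    cf = np.clip(cf, curve.clear_min, curve.clear_max)
    return float(cf) if np.isscalar(alpha) or cf.ndim == 0 else cf


def orientation_to_rgb(direction) -> np.ndarray:
    """Directionally-encoded color (DEC) of a direction vector.

    RGB = (|dx|, |dy|, |dz|) of the unit direction, the standard encoding for
    fiber orientation: left-right red, anterior-posterior green,
    superior-inferior blue.  Antipodal directions map identically.  Accepts a
    single 3-vector or an (n, 3) array.
    """
    d = np.asarray(direction, dtype=float)
    single = d.ndim == 1
    d = np.atleast_2d(d)
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero vector has no orientation")
    rgb = np.abs(d) / norms[:, None]
    return rgb[0] if single else rgb
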