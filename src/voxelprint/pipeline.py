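"""End-to-end pipeline: config schema and staged execution.

A single YAML/JSON config declares the base volume (with transfer
functions), overlay layers (volumes, tract line sets, colored meshes), hull,
palette, dither and slicing settings.  ``run_pipeline`` executes
read -> transfer -> composite -> voxelize vectors -> hull -> dither ->
slice -> write, logging per-stage voxel/segment counts, and writes a
machine-readable run summary next to the slice manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from . import io as vio
from .dither import MaterialPalette, Material, default_palette, dither_volume
from .field import OverlayLayer, OverlayStack, from_scalar_volume, make_clear_hull, overlay_fields
from .slicer import (
    DEFAULT_LAYER_UM,
    rasterize_segments_into_slice,
    slice_material_volume,
)
from .tracts import PT_TO_MM, build_interval_tree, query_slice_segments, voxelize_colored_mesh, voxelize_polylines
from .transfer import ColorLUT, OpacityCurve, window_level

__all__ = ["PipelineConfig", "PipelineError", "load_config", "run_pipeline"]

log = logging.getLogger("voxelprint")


class PipelineError(RuntimeError):
    pass


def _hex_to_rgb(value) -> tuple[float, float, float]:
    if isinstance(value, str):
        s = value.lstrip("#")
        if len(s) != 6:
            raise ValueError(f"expected #rrggbb hex color, got {value!r}")
        return tuple(int(s[i : i + 2], 16) / 255.0 for i in (0, 2, 4))
    r, g, b = value
    return float(r), float(g), float(b)


class WindowCfg(BaseModel):
    window: float = Field(gt=0)
    level: float
    clip_percentiles: Optional[tuple[float, float]] = None


class OpacityCfg(BaseModel):
    clear_min: float = 0.70
    clear_max: float = 0.95
    gamma: float = 1.0

    def build(self) -> OpacityCurve:
        return OpacityCurve(self.clear_min, self.clear_max, self.gamma)


class VolumeLayerCfg(BaseModel):
    kind: Literal["volume"] = "volume"
    path: str
    format: Optional[Literal["nifti", "dicom_series"]] = None
    threshold: tuple[float, float] = (0.0, 1.0)
    lut: list[tuple[float, object, float]] = [
        (0.0, "#000000", 0.0),
        (1.0, "#ffffff", 1.0),
    ]
    window: Optional[WindowCfg] = None
    opacity: OpacityCfg = OpacityCfg()
    keep_largest_component: bool = False
    mode: Literal["color-only", "color-and-geometry"] = "color-only"

    def build_lut(self) -> ColorLUT:
        return ColorLUT.from_points(
            [(i, _hex_to_rgb(c), a) for i, c, a in self.lut]
        )


class TractLayerCfg(BaseModel):
    kind: Literal["tracts"] = "tracts"
    path: str
    thickness_mm: Optional[float] = None
    thickness_pt: Optional[float] = None
    cross_section: Literal["circle", "triangle", "square"] = "circle"
    mode: Literal["color-only", "color-and-geometry"] = "color-and-geometry"
    print_time: bool = False  # rasterize into slices instead of voxelizing

    @property
    def thickness(self) -> float:
        if self.thickness_mm is not None:
            return self.thickness_mm
        if self.thickness_pt is not None:
            return self.thickness_pt * PT_TO_MM
        return 1.0 * PT_TO_MM


class MeshLayerCfg(BaseModel):
    kind: Literal["mesh"] = "mesh"
    path: str
    mode: Literal["color-only", "color-and-geometry"] = "color-and-geometry"


class HullCfg(BaseModel):
    enabled: bool = False
    shell_voxels: int = Field(default=1, ge=1)


class DitherCfg(BaseModel):
    seed: int = 0
    kernel: Literal["floyd-steinberg", "none"] = "floyd-steinberg"
    interlayer_fraction: float = Field(default=0.25, ge=0.0, lt=1.0)
    blue_noise_amplitude: float = Field(default=0.05, ge=0.0)


class SlicingCfg(BaseModel):
    layer_um: float = Field(default=DEFAULT_LAYER_UM, gt=0)
    pitch_mm: Optional[tuple[float, float]] = None  # None -> grid spacing


class MaterialCfg(BaseModel):
    name: str
    rgba: tuple[int, int, int, int]
    display_rgb: tuple[float, float, float]
    is_clear: bool = False


class PipelineConfig(BaseModel):
    base_volume: VolumeLayerCfg
    overlays: list[VolumeLayerCfg | TractLayerCfg | MeshLayerCfg] = []
    hull: HullCfg = HullCfg()
    palette: Optional[list[MaterialCfg]] = None  # None -> the six-resin default
    dither: DitherCfg = DitherCfg()
    slicing: SlicingCfg = SlicingCfg()
    output_dir: str = "slices"

    @field_validator("palette")
    @classmethod
    def _check_palette(cls, v):
        if v is not None and len(v) < 1:
            raise ValueError("palette must list at least one material")
        return v

    def build_palette(self) -> MaterialPalette:
        if self.palette is None:
            return default_palette()
        return MaterialPalette(
            tuple(
                Material(m.name, m.rgba, m.display_rgb, m.is_clear)
                for m in self.palette
            )
        )


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    return PipelineConfig.model_validate(data)


def _load_volume_field(cfg: VolumeLayerCfg, base_dir: Path):
    path = Path(cfg.path)
    if not path.is_absolute():
        path = base_dir / path
    if not path.exists():
        raise PipelineError(f"input not found: {path}")
    vol = vio.read_scalar_volume(path, cfg.format)
    if cfg.window is not None:
        vol = window_level(
            vol, cfg.window.window, cfg.window.level, cfg.window.clip_percentiles
        )
    field = from_scalar_volume(
        vol,
        cfg.threshold[0],
        cfg.threshold[1],
        cfg.build_lut(),
        cfg.opacity.build(),
        cfg.keep_largest_component,
    )
    return field


def run_pipeline(
    config: PipelineConfig,
    base_dir: str | Path = ".",
    seed: int | None = None,
    layer_um: float | None = None,
    pitch_mm: tuple[float, float] | None = None,
    output_dir: str | Path | None = None,
) -> Path:
    """Execute the full pipeline; returns the slice-stack manifest path.

    Keyword arguments override the corresponding config fields (CLI flags).
    The run is deterministic for a fixed config and seed.
    """
    base_dir = Path(base_dir)
    out_dir = Path(output_dir) if output_dir is not None else base_dir / config.output_dir
    dither_seed = seed if seed is not None else config.dither.seed
    layer_um = layer_um if layer_um is not None else config.slicing.layer_um
    pitch = pitch_mm if pitch_mm is not None else config.slicing.pitch_mm

    summary: dict = {"stages": []}

    def stage(name: str, **counts):
        log.info("%s: %s", name, ", ".join(f"{k}={v}" for k, v in counts.items()))
        summary["stages"].append({"stage": name, **counts})

    base = _load_volume_field(config.base_volume, base_dir)
    grid = base.grid
    stage("base_volume", solid_voxels=base.solid_count)

    overlay_layers = []
    print_time_tracts = []
    for i, ov in enumerate(config.overlays):
        if isinstance(ov, VolumeLayerCfg):
            f = _load_volume_field(ov, base_dir)
            if f.grid != grid:
                raise PipelineError(
                    f"overlay {i} grid {f.grid.dims} does not match base {grid.dims}"
                )
            overlay_layers.append(OverlayLayer(f, ov.mode))
            stage(f"overlay[{i}]:volume", solid_voxels=f.solid_count)
        elif isinstance(ov, TractLayerCfg):
            path = Path(ov.path)
            if not path.is_absolute():
                path = base_dir / path
            if not path.exists():
                raise PipelineError(f"input not found: {path}")
            lines = vio.read_tract_lines(
                path, thickness=ov.thickness, cross_section=ov.cross_section
            )
            nseg = sum(len(p.vertices) - 1 for p in lines)
            if ov.print_time:
                print_time_tracts.append(lines)
                stage(f"overlay[{i}]:tracts(print-time)", polylines=len(lines), segments=nseg)
            else:
                f = voxelize_polylines(lines, grid)
                overlay_layers.append(OverlayLayer(f, ov.mode))
                stage(
                    f"overlay[{i}]:tracts",
                    polylines=len(lines),
                    segments=nseg,
                    solid_voxels=f.solid_count,
                )
        else:  # mesh
            path = Path(ov.path)
            if not path.is_absolute():
                path = base_dir / path
            if not path.exists():
                raise PipelineError(f"input not found: {path}")
            mesh = vio.read_colored_mesh(path)
            f = voxelize_colored_mesh(mesh, grid)
            overlay_layers.append(OverlayLayer(f, ov.mode))
            stage(
                f"overlay[{i}]:mesh",
                vertices=len(mesh.vertices),
                solid_voxels=f.solid_count,
            )

    composite = overlay_fields(
        OverlayStack((OverlayLayer(base, "color-and-geometry"), *overlay_layers))
    )
    stage("composite", solid_voxels=composite.solid_count)

    if config.hull.enabled:
        composite = make_clear_hull(composite, config.hull.shell_voxels)
        stage("clear_hull", solid_voxels=composite.solid_count)

    palette = config.build_palette()
    material = dither_volume(
        composite,
        palette,
        seed=dither_seed,
        kernel=config.dither.kernel,
        interlayer_fraction=config.dither.interlayer_fraction,
        blue_noise_amplitude=config.dither.blue_noise_amplitude,
    )
    stage("dither", solid_voxels=material.solid_count, **material.material_counts())

    stack = slice_material_volume(material, layer_um, pitch)
    stage(
        "slice",
        layer_count=stack.layer_count,
        raster=f"{stack.raster_shape[1]}x{stack.raster_shape[0]}",
    )

    if print_time_tracts:
        pal_snap = palette
        th_mm = stack.layer_thickness_um / 1000.0
        total_px = 0
        for lines in print_time_tracts:
            tree = build_interval_tree(lines)
            for k, raster in enumerate(stack.layers):
                z = grid.origin[2] + (k + 0.5) * th_mm
                segs = query_slice_segments(tree, z)
                if segs:
                    before = int((raster[..., 3] != 0).sum())
                    rasterize_segments_into_slice(
                        raster, segs, z, stack.pixel_pitch_mm, pal_snap, grid.origin
                    )
                    total_px += int((raster[..., 3] != 0).sum()) - before
        stage("print_time_tracts", pixels_added=total_px)

    manifest = vio.write_slice_stack(stack, out_dir)
    stage("write", manifest=str(manifest))

    summary["seed"] = dither_seed
    summary["layer_thickness_um"] = layer_um
    summary["manifest"] = str(manifest)
    (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=1))
    return manifest
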