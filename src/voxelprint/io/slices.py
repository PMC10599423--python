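"""Printable slice-stack output: one RGBA8 PNG per layer + JSON manifest.

Every emitted raster is a 32-bit (8 bits x RGBA) PNG whose pixel values are
exact material codes from the palette (no anti-aliasing); alpha 0 encodes
void.  The manifest makes the material<->RGBA mapping, layer thickness,
pixel pitch and layer order explicit, so a stack can be decoded back into a
material volume bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from ..dither import Material, MaterialPalette
from ..slicer import SliceStack, stack_to_volume
from ..dither import MaterialVolume

__all__ = ["write_slice_stack", "read_slice_stack"]

MANIFEST_NAME = "manifest.json"


def write_slice_stack(stack: SliceStack, directory: str | Path) -> Path:
    """Write a slice stack to ``directory``; returns the manifest path.

    Layers become ``slice_0000.png`` ... (zero-padded, lexicographic =
    layer order); the JSON manifest records layer thickness (μm), xy pixel
    pitch (mm), the palette with per-material RGBA codes, and layer count.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    codes = [m.rgba_code for m in stack.palette]
    if len(set(codes)) != len(codes):
        raise ValueError("palette contains duplicate RGBA codes")

    filenames = []
    for k, raster in enumerate(stack.layers):
        name = f"slice_{k:04d}.png"
        Image.fromarray(raster, mode="RGBA").save(directory / name)
        filenames.append(name)

    manifest = {
        "layer_count": stack.layer_count,
        "layer_thickness_um": stack.layer_thickness_um,
        "pixel_pitch_mm": list(stack.pixel_pitch_mm),
        "origin_mm": list(stack.origin),
        "raster_shape": list(stack.raster_shape),
        "palette": [
            {
                "name": m.name,
                "rgba": list(m.rgba_code),
                "display_rgb": list(m.display_rgb),
                "is_clear": m.is_clear,
            }
            for m in stack.palette
        ],
        "layers": filenames,
    }
    manifest_path = directory / MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_slice_stack(directory: str | Path) -> tuple[MaterialVolume, dict]:
    """Decode a written slice stack back into a material volume.

    Layers are read in manifest order (not filename order); pixels decode to
    material indices via the manifest palette, alpha-0 pixels to void.  A
    non-palette pixel raises with its layer and pixel location.
    """
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {directory}")
    manifest = json.loads(manifest_path.read_text())

    palette = MaterialPalette(
        tuple(
            Material(
                name=m["name"],
                rgba_code=tuple(int(v) for v in m["rgba"]),
                display_rgb=tuple(float(v) for v in m["display_rgb"]),
                is_clear=bool(m.get("is_clear", False)),
            )
            for m in manifest["palette"]
        )
    )
    layers = []
    for name in manifest["layers"]:
        png = directory / name
        if not png.exists():
            raise FileNotFoundError(f"manifest lists missing layer file {name}")
        with Image.open(png) as im:
            layers.append(np.asarray(im.convert("RGBA"), dtype=np.uint8))

    stack = SliceStack(
        layers=layers,
        layer_thickness_um=float(manifest["layer_thickness_um"]),
        pixel_pitch_mm=tuple(manifest["pixel_pitch_mm"]),
        palette=palette,
        origin=tuple(manifest.get("origin_mm", (0.0, 0.0, 0.0))),
    )
    return stack_to_volume(stack), manifest
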