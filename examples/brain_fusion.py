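"""Multimodal fusion: anatomy + activation overlay + fiber tracts, to print.

A T1-like phantom is thresholded into a colored voxel field, an fMRI-like
hotspot overlay supersedes its colors where active, velocity-colored
streamlines are voxelized on the same grid and composited on top, a
one-voxel clear hull encloses everything, and the result is dithered to the
six-resin palette and sliced to printable PNG layers.
"""

import tempfile
from pathlib import Path

from voxelprint import (
    ColorLUT,
    OverlayLayer,
    OverlayStack,
    default_palette,
    dither_volume,
    from_scalar_volume,
    make_clear_hull,
    overlay_fields,
    slice_material_volume,
    voxelize_polylines,
)
from voxelprint.io import write_slice_stack
from voxelprint.phantoms import (
    ActivationPhantomSpec,
    BrainPhantomSpec,
    FlowPhantomSpec,
    make_activation_overlay,
    make_brain_phantom,
    make_flow_streamlines,
)

dims, spacing = (48, 48, 40), (0.25, 0.25, 0.25)  # 12 x 12 x 10 mm volume

anatomy = make_brain_phantom(
    BrainPhantomSpec(
        seed=1, dims=dims, spacing=spacing,
        outer_semiaxes_mm=(4.4, 5.0, 3.8), inner_semiaxes_mm=(2.8, 3.2, 2.3),
        lesion_center_offset_mm=(1.2, 0.8, 0.9), lesion_radius_mm=0.8,
        smooth_sigma_mm=0.2,
    )
)
anatomy_lut = ColorLUT.from_points(
    [(0.0, (0.2, 0.2, 0.2), 0.2), (0.55, (0.54, 0.44, 0.36), 0.4),
     (0.85, (0.91, 0.88, 0.85), 0.6), (1.0, (0.2, 0.76, 0.3), 0.95)]
)
base = from_scalar_volume(anatomy, 0.2, 1.0, anatomy_lut, keep_largest_component=True)
print(f"anatomy field: {base.solid_count} solid voxels")

activation = make_activation_overlay(
    ActivationPhantomSpec(
        seed=2, dims=dims, spacing=spacing,
        hotspots=(((6.0, 6.6, 4.8), (1.2, 1.2, 0.9), 1.0),),
    )
)
fmri_lut = ColorLUT.from_points(
    [(0.0, (1.0, 0.5, 0.0), 0.9), (1.0, (1.0, 0.15, 0.0), 1.0)]
)
overlay = from_scalar_volume(activation, 0.3, 1.0, fmri_lut)
print(f"activation overlay: {overlay.solid_count} voxels supersede anatomy color")

tracts = voxelize_polylines(
    make_flow_streamlines(
        FlowPhantomSpec(seed=3, n_lines=5, points_per_line=12, extent_mm=7.0)
    ),
    base.grid,
)
print(f"tract tubes: {tracts.solid_count} colored voxels")

fused = overlay_fields(
    OverlayStack.of(base, (overlay, "color-only"), (tracts, "color-and-geometry"))
)
hulled = make_clear_hull(fused, shell_voxels=1)
print(f"composite: {fused.solid_count} -> with clear hull: {hulled.solid_count}")

material = dither_volume(hulled, default_palette(), seed=11)
print("resin usage:", material.material_counts())

stack = slice_material_volume(material, layer_thickness_um=250.0)
out = Path(tempfile.mkdtemp()) / "slices"
manifest = write_slice_stack(stack, out)
print(f"{stack.layer_count} printable layers written, manifest at {manifest}")
print(
    "Each layer is a 32-bit RGBA PNG whose pixels are exact resin codes; "
    "alpha 0 marks void. The counts above are the per-stage audit trail."
)
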