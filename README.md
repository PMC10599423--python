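# voxelprint

Bitmap/voxel-level multimaterial 3D printing of multimodal medical imaging
data.

Surgical-planning models are usually printed from surface meshes, which
collapse graded soft-tissue contrast and make it awkward to fuse anatomy
(MRI/CT) with derived physiology (fMRI activation maps, DTI tractography,
4D-flow streamlines).  Polyjet printers, however, can be driven voxel by
voxel: each deposited droplet is one of a handful of resins, delivered as a
stack of per-layer raster images.  `voxelprint` implements that pipeline as
a library plus a thin CLI:

1. **Voxel field construction** — scalar volumes (DICOM series / NIfTI) are
   thresholded into a two-channel field: geometry (solid/void) and color
   (RGB material mix + clear-material fraction), via window/level, color
   lookup tables, and an opacity→clear-fraction compensation curve pinned to
   the 70–95 % clear band where polyjet translucency responds predictably.
2. **Compositing** — overlays supersede earlier layers hierarchically
   (color-only or color-and-geometry, strict last-wins).  Colored vector
   data (PLY streamline meshes with vertex color, legacy-VTK tract lines)
   are voxelized with nearest-vertex color inheritance; segments are indexed
   in an interval tree over z so ultra-fine curves can instead be rasterized
   per slice at print time.
3. **Material dithering** — the continuous (R, G, B, clear) mix is quantized
   to the six-resin palette (cyan, magenta, yellow, black, white, clear) by
   volumetric error diffusion: serpentine Floyd–Steinberg in-plane, 25 % of
   the residual carried to the next layer, plus a seeded blue-noise
   threshold perturbation.  Local mean mixture is preserved, so dither
   patterns reproduce graded color and translucency.
4. **Slicing** — the material volume is subdivided into 30 μm layers
   (default) and each layer written as a 32-bit RGBA PNG whose pixel values
   are exact per-resin codes (alpha 0 = void), plus a JSON manifest; the
   stack decodes back to the material volume bit-for-bit.

Seeded phantom generators (T1-like brain bands, fMRI-like hotspots,
velocity-colored streamline bundles, full-gamut dither blocks) emulate every
input modality so the whole pipeline is testable without patient data.

## Worked example

`examples/brain_fusion.py` fuses a brain phantom, an activation overlay and
streamline tubes on a 48×48×40 grid (0.25 mm voxels), encloses the result in
a clear hull, dithers and slices it:

```
anatomy field: 22815 solid voxels
activation overlay: 1455 voxels supersede anatomy color
tract tubes: 321 colored voxels
composite: 22951 -> with clear hull: 29778
resin usage: {'cyan': 147, 'magenta': 1728, 'yellow': 3258, 'black': 10132,
              'white': 0, 'clear': 14513}
40 printable layers written, manifest at .../slices/manifest.json
```

The per-stage voxel counts are the pipeline's audit trail: the overlay only
recolors existing anatomy (composite geometry grows just by the 136 tube
voxels outside the brain), the hull adds a one-voxel clear shell, and the
resin counts show the dither spending most droplets on clear material — the
translucent background that keeps embedded features visible.

Other examples: `transparency_band.py` (the opacity compensation curve),
`dither_gamut.py` (full-gamut quantization onto all six resins),
`streamline_thickness.py` (the 6 pt vs 0.25 pt thickness/saturation
trade-off and print-time curve rasterization).

## Command line

```sh
voxelprint phantom brain --seed 1 --out brain.nii.gz
voxelprint build --config pipeline.yaml --seed 11 --out slices/
voxelprint dither --in field.vxf --out material.vxf --seed 7
voxelprint slice --in material.vxf --out slices/ --layer-um 30
```

`build` runs the whole pipeline from one YAML config (inputs, LUTs,
thresholds, overlay order, hull, palette, dither and slicing settings) and
logs per-stage counts to stderr; two runs with the same config and seed
produce byte-identical slice stacks.

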