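# Methods

This note records the models, conventions and numerical choices behind
`voxelprint`, in the order data flows through the pipeline.

## Print grid and voxel field

The print volume is an axis-aligned lattice (`GridSpec`): integer dims,
positive spacing in mm per voxel, and a world origin at the corner of voxel
(0, 0, 0).  Sampling is voxel-centered (`origin + (i + 0.5)·spacing`),
world extents are half-open, and z increases with layer number (bottom-up),
which makes slice indexing unambiguous.

A `MultiChannelVoxelField` carries two channels on that grid: geometry
(solid/void) and color — an RGB material-mix triple in [0, 1] plus a
clear-material fraction in [0, 1].  Color and clear fraction are meaningful
only on solid voxels; compositing and serialization scrub them elsewhere.

**Thresholding.**  A voxel is solid iff its normalized intensity lies in the
inclusive band `[threshold_low, threshold_high]` — inclusivity is the
simplest reading of "occupied".  Optionally only the largest 26-connected
component is kept (blood pool / brain after masking); 26-connectivity is
used for components, dilation and hulls throughout because it yields
watertight shells.

**Overlays.**  Compositing is strict last-wins along the stack order, with
two override modes: color-only layers recolor existing solid voxels;
color-and-geometry layers also extend the solid set (result geometry is the
union).  No blending is performed — overlays *supersede*.  Whether a
functional overlay should replace geometry as well as color is exposed as
the mode; the default is color-only, since activation maps are usually
annotations on anatomy rather than geometry of their own.

**Clear hull.**  An enclosure "of zero thickness" cannot exist on a voxel
lattice, so the hull is the minimal printable shell: the k-voxel 26-dilation
of the solid set minus the solid set, with clear fraction 1 and a white
reference color (default k = 1).  Hull growth past the grid bounds is an
error that advises padding rather than silently clipping.

## Transfer functions

* `window_level`: linear remap taking `level` → 0.5 and `level ± window/2`
  → {0, 1}, clamped; optional percentile clipping (default suggestion
  0.5/99.5) stands in for unspecified "histogram processing" and runs before
  the window.
* `ColorLUT`: piecewise-linear color/opacity control points on [0, 1],
  exact at control points, clamped outside the domain.
* `compensate_transparency`: perceived polyjet translucency is nonlinear in
  the clear mixing ratio and only controllable in roughly the 70–95 % clear
  band, so opacity α maps through the bounded power curve
  `clear = clear_max − (clear_max − clear_min)·α^γ` with defaults
  `clear_min = 0.70`, `clear_max = 0.95`, `γ = 1`.  The band endpoints are
  the only hard constraint; γ is a user-editable calibration knob because no
  transfer standard exists for a given printer/resin batch (digital-to-print
  appearance is calibrated iteratively in practice).
* `orientation_to_rgb`: directionally-encoded color, RGB = |unit
  direction| — the community convention for fiber orientation; antipodal
  directions map identically.

## Vector data: tubes, meshes, interval tree

Polylines carry per-vertex RGB, a swept **diameter** (`thickness`, mm; pt
accepted at 1 pt = 25.4/72 mm) and a cross-section shape.  Circular
cross-sections use the rounded-cap distance-to-centerline test; square and
triangle profiles (circumradius = radius) are evaluated with flat caps in a
parallel-transported frame seeded from global +z (fallback +x when the
tangent is parallel to z) — deterministic and continuous; no orientation
rule is standard, so one had to be fixed.

Voxel colors inherit from the **nearest vertex** (not interpolated along
edges); distance ties break to the lowest vertex of the lowest polyline id
for reproducibility.  Nearest-vertex lookup uses a k-d tree with an
explicit tie scan.

Closed colored meshes are filled by parity ray casting along z columns
(sample columns nudged by a sub-nanometer-irrelevant ~1e-5 mm offset so rays
never hit edges exactly); a generalized-winding-number test is kept as an
independent slow path.  Non-watertight meshes are rejected with their open
edge count.

Segments are indexed by their radius-inflated closed z-interval
`[min z − r, max z + r]` in an interval tree (backed by the `intervaltree`
package; the upper bound is padded by one ulp to obtain closed-interval
stabbing).  Slice-time rasterization queries the tree at the layer's
mid-height and paints pixels whose centers fall inside the swept section,
with endpoint colors interpolated along the segment and snapped to the
nearest palette code; this is the intended path for sub-voxel-thin curves,
while full-grid voxelization remains available for compositing.

## Dithering

Targets live in a 4-space: (R, G, B, clear fraction).  Each palette material
contributes its display RGB and a clear coordinate of 0, except the clear
resin at (1, 1, 1, 1) — clear mixes along the fourth coordinate rather than
as a color.  Quantization picks the nearest material by Euclidean distance
(ties to the lowest palette index).

The cited volumetric blue-noise error-diffusion dither has no published
kernel, so the implemented kernel is a documented stand-in validated by
mean preservation, not by equivalence: serpentine Floyd–Steinberg weights
(7/16, 3/16, 5/16, 1/16) in-plane, a fixed fraction (default 25 %) of the
residual passed to the voxel directly above in the next layer, and a seeded
blue-noise threshold perturbation (white Gaussian noise minus its Gaussian
blur, σ = 1.5 voxels, unit-normalized, amplitude 0.05 per channel) added
only to the *decision* input — the diffused residual is computed from the
unperturbed value, so the perturbation decorrelates worm artifacts without
biasing the mean.  All three elements are switchable for kernel comparison.

Mean preservation holds for **in-gamut** targets (inside the convex hull of
the palette's mixing vectors); empirically ‖mean error‖∞ ≤ 3/n on uniform
n³ blocks.  Out-of-gamut targets (e.g. a saturated color demanded together
with a high clear fraction) are clamped before the nearest-material choice
and the residual is bounded at ±4 per channel, so the output converges to
the nearest attainable mixture instead of diverging.  Void voxels are never
assigned and never consume diffused error.

The default palette mirrors a six-resin Stratasys J750-class loadout
(VeroCyan, VeroMagenta, VeroYellow, VeroBlackPlus, VeroPureWhite,
VeroClear).  Slice rasters identify materials by exact RGBA codes; clear
shares white's RGB and is distinguished by alpha 128.

## Slicing

`layer_count = ceil(z_extent / layer_thickness)` (with a 1e-9 relative
tolerance so exact ratios do not round up); each layer samples the material
volume by nearest-voxel lookup at pixel centers at the layer's **mid**
height — the symmetric representative of the block.  Default layer
thickness is 30 μm; the xy pixel pitch defaults to the grid spacing
(lossless, slicing∘stacking = identity) and the CLI default is
(25.4/600, 25.4/300) mm — a 600×300 dpi print-head class, since no droplet
pitch is standardized.  A pitch differing from the grid spacing requires the
explicit `resample="nearest"` policy.  The original workflow rendered each
30 μm block with a virtual camera; direct orthographic nearest-voxel
rasterization replaces that with an identical output contract and
bit-reproducible slices.  Dithering happens in 3-D before slicing (slices
are lossless), with print-time curve rasterization as the stated exception.

Output is one RGBA8 PNG per layer (32 bits per pixel, zero-padded
filenames, lexicographic = layer order) plus a JSON manifest (layer
thickness, pitch, palette codes, layer order, grid origin).  Decoding
follows the manifest order, maps alpha-0 pixels to void, and fails loudly
on any pixel outside the palette.

## Phantoms

The generators imitate statistical structure, not anatomy:

* **Brain**: nested smoothed ellipsoids — background ≈ 0, gray-matter band
  0.50, white-matter band 0.80, optional lesion blob 0.95 — Gaussian
  smoothing σ = 0.8 mm and 2 % Gaussian texture noise inside the head mask;
  default grid 170 axial slices at 1 mm isotropic, matching a typical T1
  acquisition.  Half-band thresholds recover region boundaries, so region
  voxel counts agree with analytic ellipsoid volumes to a few percent.
* **Activation**: a sum of anisotropic Gaussian hotspots plus seeded
  uniform noise (default amplitude 0.05) that thresholding must eliminate;
  the maximum sits at a declared hotspot center.
* **Flow streamlines**: helical arcs with a mid-arc-peaked speed profile,
  normalized so the set's peak hits the declared maximum exactly and maps
  to the top of the blue→red velocity LUT; default 25 lines, 1 pt diameter.
* **Gamut block**: every voxel solid; each of the four channels is an
  independently shuffled evenly spaced sample of [0, 1] (uniform histograms
  by construction) with the first six voxels pinned to the palette's exact
  mixing targets.

Every generator is a pure function of its spec (one explicit seed, no
global state).  What passing tests on phantoms do **not** show: robustness
to scanner artifacts, bias fields, registration error, or anatomical
geometry — the phantoms have none of those.

## Problem sizes and limitations

The test suite exercises oracle comparisons at 32³ grids, dither
convergence at up to 64³, interval-tree properties at 10³ segments × 10²
planes, and end-to-end builds on ~32³ phantom volumes with 0.25 mm voxels —
sizes chosen so the full suite runs in well under a minute per property
while keeping boundary effects representative.  Known limitations: DICOM
reading rejects gantry-tilted and nonuniformly spaced series rather than
resampling them; no ICC/appearance modeling of cured resin (the opacity
curve is a band-constrained heuristic); no mesh repair; no printer job
submission.
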