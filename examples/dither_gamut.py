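"""Volumetric error-diffusion dithering of a full-gamut color block.

A 32^3 block whose voxels sample the whole (RGB, clear) mixing space is
quantized to the six printable resins.  Local mean color is preserved by
serpentine Floyd-Steinberg diffusion in-plane plus 25% error carry to the
next layer, decorrelated by a seeded blue-noise threshold perturbation.
"""

from voxelprint import default_palette, dither_volume
from voxelprint.phantoms import GamutPhantomSpec, make_gamut_block

field = make_gamut_block(GamutPhantomSpec(seed=0))
material = dither_volume(field, default_palette(), seed=1)

counts = material.material_counts()
total = material.solid_count
print(f"dithered {total} voxels onto {len(counts)} resins:")
for name, n in counts.items():
    print(f"  {name:8s} {n:6d}  ({100 * n / total:5.1f}%)")
print(
    "\nEvery resin is used; the shares reflect how much of the mixing space "
    "each material's quantization cell covers, not equal parts."
)
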