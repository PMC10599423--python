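"""Scalar intensity volumes (MRI / CT / fMRI input)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec

__all__ = ["ScalarVolume"]


@dataclass
class ScalarVolume:
    """A 3-D scalar intensity lattice with grid metadata.

    Intensities are stored normalized to [0, 1] (min-max over the source
    data); ``source_bit_depth`` records the bit depth of the file the volume
    was read from (8 or 16).  Array axis order is (x, y, z).
    """

    grid: GridSpec
    intensities: np.ndarray = field(repr=False)
    source_bit_depth: int = 16

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.shape != self.grid.dims:
            raise ValueError(
                f"intensity lattice shape {arr.shape} does not match grid dims "
                f"{self.grid.dims}"
            )
        if arr.size and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
            raise ValueError("intensities must lie in [0, 1]")
        if self.source_bit_depth not in (8, 16):
            raise ValueError("source_bit_depth must be 8 or 16")
        self.intensities = np.clip(arr, 0.0, 1.0)

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.intensities.copy(), self.source_bit_depth)
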