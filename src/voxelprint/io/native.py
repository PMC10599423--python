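"""Native chunked binary container for voxel fields (intermediate results).

Layout: magic ``VXF1``, an 8-byte little-endian header length, a JSON header
(dims, spacing, origin, ordered channel descriptions with dtype and shape),
then one raw C-order chunk per channel.  This is pipeline plumbing, not a
printer format.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from ..dither import Material, MaterialPalette, MaterialVolume
from ..field import MultiChannelVoxelField
from ..grid import GridSpec

__all__ = ["save_field", "load_field", "save_material_volume", "load_material_volume"]

_MAGIC = b"VXF1"


def _write(path: Path, grid: GridSpec, channels: list[tuple[str, np.ndarray]], extra: dict):
    header = {
        "dims": list(grid.dims),
        "spacing": list(grid.spacing),
        "origin": list(grid.origin),
        "channels": [
            {"name": name, "dtype": str(arr.dtype), "shape": list(arr.shape)}
            for name, arr in channels
        ],
        **extra,
    }
    blob = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<Q", len(blob)))
        fh.write(blob)
        for _, arr in channels:
            fh.write(np.ascontiguousarray(arr).tobytes())


def _read(path: Path) -> tuple[dict, dict[str, np.ndarray]]:
    with open(path, "rb") as fh:
        if fh.read(4) != _MAGIC:
            raise ValueError(f"{path} is not a native voxel-field file")
        (hlen,) = struct.unpack("<Q", fh.read(8))
        header = json.loads(fh.read(hlen).decode())
        chunks = {}
        for ch in header["channels"]:
            shape = tuple(ch["shape"])
            dtype = np.dtype(ch["dtype"])
            n = int(np.prod(shape)) * dtype.itemsize
            chunks[ch["name"]] = np.frombuffer(fh.read(n), dtype=dtype).reshape(shape)
    return header, chunks


def save_field(field: MultiChannelVoxelField, path: str | Path) -> Path:
    path = Path(path)
    _write(
        path,
        field.grid,
        [
            ("geometry", field.geometry.astype(np.uint8)),
            ("color", field.color.astype(np.float32)),
            ("clear_fraction", field.clear_fraction.astype(np.float32)),
        ],
        {"kind": "multichannel_field"},
    )
    return path


def load_field(path: str | Path) -> MultiChannelVoxelField:
    header, chunks = _read(Path(path))
    if header.get("kind") != "multichannel_field":
        raise ValueError(f"{path} does not contain a multichannel field")
    grid = GridSpec(
        tuple(header["dims"]), tuple(header["spacing"]), tuple(header["origin"])
    )
    return MultiChannelVoxelField(
        grid,
        chunks["geometry"].astype(bool),
        chunks["color"].astype(np.float64),
        chunks["clear_fraction"].astype(np.float64),
    )


def save_material_volume(volume: MaterialVolume, path: str | Path) -> Path:
    path = Path(path)
    _write(
        path,
        volume.grid,
        [("assignment", volume.assignment.astype(np.int16))],
        {
            "kind": "material_volume",
            "palette": [
                {
                    "name": m.name,
                    "rgba": list(m.rgba_code),
                    "display_rgb": list(m.display_rgb),
                    "is_clear": m.is_clear,
                }
                for m in volume.palette
            ],
        },
    )
    return path


def load_material_volume(path: str | Path) -> MaterialVolume:
    header, chunks = _read(Path(path))
    if header.get("kind") != "material_volume":
        raise ValueError(f"{path} does not contain a material volume")
    grid = GridSpec(
        tuple(header["dims"]), tuple(header["spacing"]), tuple(header["origin"])
    )
    palette = MaterialPalette(
        tuple(
            Material(
                m["name"],
                tuple(int(v) for v in m["rgba"]),
                tuple(float(v) for v in m["display_rgb"]),
                bool(m["is_clear"]),
            )
            for m in header["palette"]
        )
    )
    return MaterialVolume(grid, palette, chunks["assignment"])
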