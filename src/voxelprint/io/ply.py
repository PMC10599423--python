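"""PLY meshes with per-vertex RGB (streamline surfaces).

ASCII and binary-little-endian PLY are supported through trimesh; byte
colors are rescaled to [0, 1].  A PLY without red/green/blue vertex
properties is rejected, since the whole point of the format here is the
vertex color carrying the physiology encoding.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh

from ..tracts import ColoredMesh

__all__ = ["read_colored_mesh", "write_colored_mesh"]

_COLOR_PROPS = ("red", "green", "blue")


def _header_color_props(path: Path) -> set[str]:
    """Vertex color property names declared in the PLY header."""
    props: set[str] = set()
    in_vertex = False
    with open(path, "rb") as fh:
        for raw in fh:
            line = raw.decode("ascii", errors="replace").strip()
            if line.startswith("element"):
                in_vertex = line.split()[1] == "vertex"
            elif line.startswith("property") and in_vertex:
                name = line.split()[-1]
                if name in _COLOR_PROPS:
                    props.add(name)
            elif line == "end_header":
                break
    return props


def read_colored_mesh(path: str | Path) -> ColoredMesh:
    """Read a PLY mesh, requiring per-vertex red/green/blue properties."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    present = _header_color_props(path)
    missing = [p for p in _COLOR_PROPS if p not in present]
    if missing:
        raise ValueError(
            f"PLY {path.name} lacks vertex color propert"
            f"{'y' if len(missing) == 1 else 'ies'}: {', '.join(missing)}"
        )
    mesh = trimesh.load(str(path), file_type="ply", process=False)
    colors = np.asarray(mesh.visual.vertex_colors, dtype=float)[:, :3] / 255.0
    return ColoredMesh(
        vertices=np.asarray(mesh.vertices, dtype=float),
        colors=colors,
        faces=np.asarray(mesh.faces, dtype=np.int64),
    )


def write_colored_mesh(
    mesh: ColoredMesh, path: str | Path, encoding: str = "binary"
) -> Path:
    """Write a colored mesh to PLY (``encoding``: "ascii" or "binary")."""
    path = Path(path)
    rgba = np.column_stack(
        [
            np.clip(np.round(mesh.colors * 255), 0, 255).astype(np.uint8),
            np.full(len(mesh.vertices), 255, dtype=np.uint8),
        ]
    )
    tm = trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.faces, vertex_colors=rgba, process=False
    )
    tm.export(str(path), encoding=encoding)
    return path
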