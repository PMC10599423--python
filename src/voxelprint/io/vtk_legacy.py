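"""Legacy VTK polydata line sets (DTI tractography fibers).

Tractography pipelines commonly store fiber curves as legacy (ASCII) VTK
polydata: a POINTS block, a LINES connectivity block (one record per fiber,
each with a unique index), and optionally per-point colors.  When no colors
are present, vertices are colored by the directionally-encoded-color (DEC)
convention from the local fiber direction.

Only the classic ASCII format is handled (no XML, no binary, no VTK 5.x
OFFSETS/CONNECTIVITY layout).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ..tracts import PT_TO_MM, ColoredPolylineSet, Polyline
from ..transfer import orientation_to_rgb

__all__ = ["read_tract_lines", "write_tract_lines"]


def _local_directions(vertices: np.ndarray) -> np.ndarray:
    """Per-vertex local segment direction (central differences at interior)."""
    d = np.empty_like(vertices)
    d[0] = vertices[1] - vertices[0]
    d[-1] = vertices[-1] - vertices[-2]
    if len(vertices) > 2:
        d[1:-1] = vertices[2:] - vertices[:-2]
    return d


def read_tract_lines(
    path: str | Path,
    thickness: float = 1.0 * PT_TO_MM,
    thickness_pt: float | None = None,
    cross_section: str = "circle",
) -> ColoredPolylineSet:
    """Parse a legacy VTK polydata file into a colored polyline set.

    One polyline per LINES record, id = record index.  Per-point RGB is
    taken from a COLOR_SCALARS (or 3-component SCALARS) block if present,
    rescaled to [0, 1] (values above 1 are assumed byte-scaled); otherwise
    each vertex is colored by ``orientation_to_rgb`` of its local fiber
    direction.  ``thickness`` is the tube diameter in mm (or pass
    ``thickness_pt`` in printer's points, 1 pt = 25.4/72 mm).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if thickness_pt is not None:
        thickness = thickness_pt * PT_TO_MM

    tokens: list[str] = []
    tok_lines: list[int] = []
    with open(path, "r") as fh:
        lines = fh.readlines()
    # skip the two header lines (version + title); tokenize the rest lazily
    body_start = 2
    for lineno, line in enumerate(lines[body_start:], start=body_start):
        for t in line.split():
            tokens.append(t)
            tok_lines.append(lineno + 1)

    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take(n: int = 1) -> list[str]:
        nonlocal pos
        if pos + n > len(tokens):
            raise ValueError(f"{path.name}: unexpected end of file")
        out = tokens[pos : pos + n]
        pos += n
        return out

    fmt = take(1)[0].upper()
    if fmt != "ASCII":
        raise ValueError(f"{path.name}: only ASCII legacy VTK is supported")
    kw, kind = take(2)
    if kw.upper() != "DATASET" or kind.upper() != "POLYDATA":
        raise ValueError(f"{path.name}: expected DATASET POLYDATA, got {kind}")

    points: np.ndarray | None = None
    conn: list[np.ndarray] = []
    colors: np.ndarray | None = None

    while (word := peek()) is not None:
        word = word.upper()
        if word == "POINTS":
            _, n, _dtype = take(3)
            n = int(n)
            vals = np.array(take(3 * n), dtype=float)
            points = vals.reshape(n, 3)
        elif word == "LINES":
            _, nrec, _total = take(3)
            for _ in range(int(nrec)):
                cnt = int(take(1)[0])
                idx = np.array(take(cnt), dtype=np.int64)
                conn.append(idx)
        elif word == "POINT_DATA":
            _, n = take(2)
            n = int(n)
        elif word == "COLOR_SCALARS":
            _, _name, ncomp = take(3)
            ncomp = int(ncomp)
            if points is None:
                raise ValueError(f"{path.name}: COLOR_SCALARS before POINTS")
            vals = np.array(take(ncomp * len(points)), dtype=float)
            colors = vals.reshape(len(points), ncomp)[:, :3]
        elif word == "SCALARS":
            _, _name, _dtype = take(3)
            ncomp = 1
            if peek() and peek().isdigit():
                ncomp = int(take(1)[0])
            if peek() and peek().upper() == "LOOKUP_TABLE":
                take(2)
            if points is None:
                raise ValueError(f"{path.name}: SCALARS before POINTS")
            vals = np.array(take(ncomp * len(points)), dtype=float)
            if ncomp >= 3:
                colors = vals.reshape(len(points), ncomp)[:, :3]
        else:
            raise ValueError(f"{path.name}: unsupported section {word!r}")

    if points is None or not conn:
        raise ValueError(f"{path.name}: no POINTS/LINES polydata found")
    if colors is not None and colors.max() > 1.0:
        colors = colors / 255.0

    polylines = []
    for rec_id, idx in enumerate(conn):
        if idx.min() < 0 or idx.max() >= len(points):
            raise ValueError(
                f"{path.name}: line record {rec_id} references point "
                f"{int(idx.max())} outside 0..{len(points) - 1}"
            )
        verts = points[idx]
        if colors is not None:
            vcol = np.clip(colors[idx], 0.0, 1.0)
        else:
            vcol = orientation_to_rgb(_local_directions(verts))
        polylines.append(
            Polyline(
                id=rec_id,
                vertices=verts,
                vertex_colors=vcol,
                thickness=thickness,
                cross_section=cross_section,
            )
        )
    return ColoredPolylineSet(polylines)


def write_tract_lines(
    lines: ColoredPolylineSet,
    path: str | Path,
    include_colors: bool = True,
    title: str = "synthetic tract lines",
) -> Path:
    """Write a polyline set as legacy ASCII VTK polydata (fixture emitter)."""
    path = Path(path)
    order = sorted(lines.polylines, key=lambda p: p.id)
    counts = [len(p.vertices) for p in order]
    total_pts = sum(counts)
    offsets = np.cumsum([0] + counts[:-1])
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {total_pts} float\n")
        for p in order:
            for v in p.vertices:
                fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        fh.write(f"LINES {len(order)} {total_pts + len(order)}\n")
        for p, off in zip(order, offsets):
            idx = " ".join(str(off + i) for i in range(len(p.vertices)))
            fh.write(f"{len(p.vertices)} {idx}\n")
        if include_colors:
            fh.write(f"POINT_DATA {total_pts}\n")
            fh.write("COLOR_SCALARS colors 3\n")
            for p in order:
                for c in p.vertex_colors:
                    fh.write(f"{c[0]:.6f} {c[1]:.6f} {c[2]:.6f}\n")
    return path
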