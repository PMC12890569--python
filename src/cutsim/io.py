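"""Export helpers: point clouds with per-particle attributes, run records.

Clouds are written as ASCII PLY (xyz + radius + body id + arbitrary scalar
properties) and legacy-VTK polydata so they open directly in ParaView or
CloudCompare for damage-heatmap inspection.  Solids go through trimesh's
STL support.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

__all__ = ["write_ply", "write_vtk", "write_json", "file_checksum"]


def write_ply(
    path,
    points: np.ndarray,
    comment: str = "",
    **scalars: np.ndarray,
) -> None:
    """Write a point cloud with named scalar properties as ASCII PLY."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    cols = [points[:, 0], points[:, 1], points[:, 2]]
    names = ["x", "y", "z"]
    types = ["float"] * 3
    for name, arr in scalars.items():
        arr = np.asarray(arr)
        if len(arr) != n:
            raise ValueError(f"scalar {name!r} length mismatch")
        is_int = np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool
        cols.append(arr.astype(np.int64 if is_int else float))
        names.append(name)
        types.append("int" if is_int else "float")

    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        if comment:
            fh.write(f"comment {comment}\n")
        fh.write(f"element vertex {n}\n")
        for name, typ in zip(names, types):
            fh.write(f"property {typ} {name}\n")
        fh.write("end_header\n")
        for row in zip(*cols):
            fh.write(
                " ".join(
                    str(int(v)) if isinstance(v, (np.integer, int)) else f"{v:.6g}"
                    for v in row
                )
                + "\n"
            )


def write_vtk(path, points: np.ndarray, **scalars: np.ndarray) -> None:
    """Write a point cloud as legacy-VTK polydata with point-data scalars."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncutsim cloud\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        for p in points:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        fh.write(f"VERTICES {n} {2 * n}\n")
        for i in range(n):
            fh.write(f"1 {i}\n")
        if scalars:
            fh.write(f"POINT_DATA {n}\n")
            for name, arr in scalars.items():
                arr = np.asarray(arr, dtype=float)
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for v in arr:
                    fh.write(f"{v:.6g}\n")


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
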