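"""Minimal legacy-ASCII VTK writers for meshes and flow fields.

Output is plain text, viewable in ParaView.  Only what the package needs:
unstructured grids of tetrahedra/triangles with optional point data, and
rectilinear grids with cell data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_CELL_TYPES = {3: 5, 4: 10}  # triangle, tetrahedron


def write_unstructured(
    path: str | Path,
    points: np.ndarray,
    cells: np.ndarray,
    point_data: dict[str, np.ndarray] | None = None,
    comment: str = "pillartrap mesh",
) -> None:
    points = np.asarray(points, dtype=float)
    if points.shape[1] == 2:
        points = np.column_stack([points, np.zeros(len(points))])
    cells = np.asarray(cells, dtype=int)
    npts, ncell = len(points), len(cells)
    nverts = cells.shape[1]
    ctype = _CELL_TYPES[nverts]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(comment.replace("\n", " ")[:250] + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {npts} float\n")
        np.savetxt(fh, points, fmt="%.8g")
        fh.write(f"CELLS {ncell} {ncell * (nverts + 1)}\n")
        np.savetxt(fh, np.column_stack([np.full(ncell, nverts), cells]), fmt="%d")
        fh.write(f"CELL_TYPES {ncell}\n")
        np.savetxt(fh, np.full(ncell, ctype), fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {npts}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%.8g")
                else:
                    fh.write(f"VECTORS {name} float\n")
                    if arr.shape[1] == 2:
                        arr = np.column_stack([arr, np.zeros(len(arr))])
                    np.savetxt(fh, arr, fmt="%.8g")


def write_rectilinear(
    path: str | Path,
    xf: np.ndarray,
    yf: np.ndarray,
    cell_data: dict[str, np.ndarray],
    comment: str = "pillartrap flow field",
) -> None:
    """2D rectilinear grid (faces xf, yf in um) with per-cell scalars."""
    xf = np.asarray(xf, dtype=float)
    yf = np.asarray(yf, dtype=float)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(comment.replace("\n", " ")[:250] + "\n")
        fh.write("ASCII\nDATASET RECTILINEAR_GRID\n")
        fh.write(f"DIMENSIONS {len(xf)} {len(yf)} 1\n")
        fh.write(f"X_COORDINATES {len(xf)} float\n")
        np.savetxt(fh, xf[None], fmt="%.8g")
        fh.write(f"Y_COORDINATES {len(yf)} float\n")
        np.savetxt(fh, yf[None], fmt="%.8g")
        fh.write("Z_COORDINATES 1 float\n0\n")
        ncell = (len(xf) - 1) * (len(yf) - 1)
        fh.write(f"CELL_DATA {ncell}\n")
        for name, arr in cell_data.items():
            arr = np.asarray(arr, dtype=float)
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # VTK expects x varying fastest: arr is (nx, ny) -> transpose
            np.savetxt(fh, arr.T.ravel(), fmt="%.8g")
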