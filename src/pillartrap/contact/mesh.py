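"""Tetrahedral meshing of a spherical cell.

The ball is meshed with a "spherified cube": a structured (n+1)^3 vertex
lattice on the cube [-1, 1]^3 is mapped radially onto the unit ball by

    q = p * |p|_inf / |p|_2        (q = 0 for p = 0)

which is a smooth bijection of the cube onto the ball, each hexahedral lattice
cell is split into six tetrahedra sharing a main diagonal, and the node cloud
is finally rescaled so the discrete mesh volume matches the requested sphere
volume exactly (the piecewise-linear boundary otherwise under-estimates the
volume by O(1/n^2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidInputError, MeshError

__all__ = ["CellMesh", "build_cell_mesh", "tet_volumes", "surface_triangles"]

# six tets per hex, all sharing the 0-6 diagonal (vertices in VTK hex order
# 0:(0,0,0) 1:(1,0,0) 2:(1,1,0) 3:(0,1,0) 4:(0,0,1) 5:(1,0,1) 6:(1,1,1) 7:(0,1,1))
_HEX_TO_TETS = np.array(
    [
        [0, 1, 2, 6],
        [0, 2, 3, 6],
        [0, 3, 7, 6],
        [0, 7, 4, 6],
        [0, 4, 5, 6],
        [0, 5, 1, 6],
    ]
)


@dataclass(frozen=True)
class CellMesh:
    """nodes (N, 3) um; elements (M, 4) tet connectivity; surface (S, 3)
    outward-oriented boundary triangles; resolution = lattice divisions."""

    nodes: np.ndarray
    elements: np.ndarray
    surface: np.ndarray
    resolution: int

    @property
    def volume(self) -> float:
        return float(tet_volumes(self.nodes, self.elements).sum())

    @property
    def centroid(self) -> np.ndarray:
        vols = tet_volumes(self.nodes, self.elements)
        cents = self.nodes[self.elements].mean(axis=1)
        return (vols[:, None] * cents).sum(axis=0) / vols.sum()


def tet_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Signed volumes of all tets."""
    x = nodes[elements]
    d1, d2, d3 = x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]
    return np.einsum("ij,ij->i", d1, np.cross(d2, d3)) / 6.0


def surface_triangles(elements: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Boundary faces (those owned by exactly one tet), oriented outward."""
    faces = elements[:, [[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    boundary = faces[idx[counts == 1]]
    # orient outward: flip triangles whose normal points toward the centroid
    centroid = nodes.mean(axis=0)
    p0, p1, p2 = nodes[boundary[:, 0]], nodes[boundary[:, 1]], nodes[boundary[:, 2]]
    normals = np.cross(p1 - p0, p2 - p0)
    outward = np.einsum("ij,ij->i", normals, (p0 + p1 + p2) / 3 - centroid) > 0
    boundary[~outward] = boundary[~outward][:, ::-1]
    return boundary


def build_cell_mesh(diameter: float, resolution: int = 4) -> CellMesh:
    """Mesh a sphere of the given diameter (um).

    ``resolution`` is the number of lattice divisions per cube axis; the mesh
    has (resolution+1)^3 nodes and 6*resolution^3 tets.  The default of 4
    (125 nodes, 384 tets) is the desk-scale compromise used throughout the
    critical-pressure sweeps.
    """
    if not diameter > 0:
        raise InvalidInputError(f"diameter must be > 0, got {diameter}")
    if resolution < 2:
        raise InvalidInputError("resolution must be >= 2")
    n = resolution
    s = np.linspace(-1.0, 1.0, n + 1)
    X, Y, Z = np.meshgrid(s, s, s, indexing="ij")
    p = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    norm2 = np.linalg.norm(p, axis=1)
    norminf = np.max(np.abs(p), axis=1)
    scale = np.divide(norminf, norm2, out=np.ones_like(norm2), where=norm2 > 0)
    nodes = p * scale[:, None]

    def vid(i, j, k):
        return (i * (n + 1) + j) * (n + 1) + k

    hexes = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                hexes.append(
                    [
                        vid(i, j, k),
                        vid(i + 1, j, k),
                        vid(i + 1, j + 1, k),
                        vid(i, j + 1, k),
                        vid(i, j, k + 1),
                        vid(i + 1, j, k + 1),
                        vid(i + 1, j + 1, k + 1),
                        vid(i, j + 1, k + 1),
                    ]
                )
    hexes = np.asarray(hexes)
    elements = hexes[:, _HEX_TO_TETS].reshape(-1, 4)

    vols = tet_volumes(nodes, elements)
    if np.any(vols <= 0):
        # fix orientation of any negatively-oriented tets
        bad = vols < 0
        elements[bad] = elements[bad][:, [0, 1, 3, 2]]
        vols = tet_volumes(nodes, elements)
        if np.any(vols <= 0):
            raise MeshError("degenerate tetrahedra in spherified-cube mesh")

    # calibrate: rescale so the discrete volume equals the sphere volume
    target = 4.0 / 3.0 * np.pi * (diameter / 2.0) ** 3
    nodes = nodes * (diameter / 2.0)
    vol = float(tet_volumes(nodes, elements).sum())
    nodes *= (target / vol) ** (1.0 / 3.0)

    surface = surface_triangles(elements, nodes)
    return CellMesh(
        nodes=nodes, elements=elements, surface=surface, resolution=resolution
    )
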