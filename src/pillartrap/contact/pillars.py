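"""Rigid diamond-pillar pair and its signed-distance contact surface.

The trapping unit is two diamond prisms facing across a gap in y, flow along
x, prisms extruded in z.  The pillars are ~3000x stiffer than the cells, so
they are rigid and static.  Vertex fillets are modelled exactly by rounding:
the filleted diamond is the Minkowski sum of an inset diamond with a disk of
the fillet radius, so its signed distance is (distance to the inset polygon)
minus the fillet radius.  Pillar centres are placed so the minimum clearance
between the two *rounded* surfaces equals the requested gap.

The cell never reaches the channel floor/ceiling (cell diameter < pillar
height), so contact uses the 2D cross-section distance at every z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidGeometryError
from ..types import TrapGeometry

__all__ = ["RigidSurface", "build_pillar_surface", "polygon_signed_distance"]


def polygon_signed_distance(points_xy: np.ndarray, poly: np.ndarray):
    """Signed distance (negative inside) from 2D points to a simple polygon,
    plus the closest boundary points.  Vectorized over points."""
    p = np.atleast_2d(np.asarray(points_xy, dtype=float))
    a = poly
    b = np.roll(poly, -1, axis=0)
    ab = b - a  # (m, 2)
    ap = p[:, None, :] - a[None, :, :]  # (n, m, 2)
    t = np.clip(
        np.einsum("nmk,mk->nm", ap, ab) / np.einsum("mk,mk->m", ab, ab), 0.0, 1.0
    )
    closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d2 = np.sum((p[:, None, :] - closest) ** 2, axis=2)
    j = np.argmin(d2, axis=1)
    dist = np.sqrt(d2[np.arange(len(p)), j])
    nearest = closest[np.arange(len(p)), j]
    # inside test by crossing number
    inside = np.zeros(len(p), dtype=bool)
    for (ax, ay), (bx, by) in zip(a, b):
        cond = (ay > p[:, 1]) != (by > p[:, 1])
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = (bx - ax) * (p[:, 1] - ay) / (by - ay) + ax
        inside ^= cond & (p[:, 0] < xint)
    return np.where(inside, -dist, dist), nearest


@dataclass(frozen=True)
class RigidSurface:
    """Contact representation of the pillar pair.

    ``inset_polys`` are the two fillet-inset diamonds; the physical surface
    is the offset set {sdf_inset = fillet}.  ``triangles``/``points`` give a
    triangulated prism surface for export and facet queries.
    """

    geometry: TrapGeometry
    inset_polys: tuple[np.ndarray, np.ndarray]
    fillet: float
    gap_throat_plane: float
    points: np.ndarray = field(repr=False)
    triangles: np.ndarray = field(repr=False)

    def signed_distance(self, points_xy: np.ndarray) -> np.ndarray:
        """Distance to the nearest rounded pillar surface; negative inside."""
        d0, _ = polygon_signed_distance(points_xy, self.inset_polys[0])
        d1, _ = polygon_signed_distance(points_xy, self.inset_polys[1])
        return np.minimum(d0, d1) - self.fillet

    def signed_distance_grad(self, points_xy: np.ndarray):
        """(sdf, unit outward gradient) at the given 2D points."""
        p = np.atleast_2d(points_xy)
        d0, c0 = polygon_signed_distance(p, self.inset_polys[0])
        d1, c1 = polygon_signed_distance(p, self.inset_polys[1])
        use0 = d0 <= d1
        d = np.where(use0, d0, d1)
        c = np.where(use0[:, None], c0, c1)
        vec = p - c
        norm = np.linalg.norm(vec, axis=1)
        # sign convention: gradient always points from solid towards fluid
        grad = np.where(
            norm[:, None] > 1e-12, vec / np.maximum(norm, 1e-12)[:, None], 0.0
        )
        return d - self.fillet, grad

    def min_clearance(self, n_samples: int = 2000) -> float:
        """Minimum distance between the two rounded pillar surfaces,
        estimated by sampling boundary points of one pillar and evaluating
        the distance field of the other."""
        pts = _rounded_boundary(self.inset_polys[0], self.fillet, n_samples)
        d, _ = polygon_signed_distance(pts, self.inset_polys[1])
        return float(np.min(d - self.fillet))


def _diamond(center: np.ndarray, d_major: float, d_minor: float) -> np.ndarray:
    cx, cy = center
    return np.array(
        [
            [cx + d_major / 2, cy],
            [cx, cy + d_minor / 2],
            [cx - d_major / 2, cy],
            [cx, cy - d_minor / 2],
        ]
    )


def _inset_diamond(center, d_major, d_minor, rho):
    """Diamond whose edges are moved inward by rho (edge-offset inset)."""
    # half-angle at the minor-axis vertex: sin = d_major / diag_edge_len*?
    edge = np.hypot(d_major / 2, d_minor / 2)
    sin_minor = (d_major / 2) / edge  # between edge and the minor axis
    sin_major = (d_minor / 2) / edge
    shrink_minor = rho / sin_minor  # vertex retreat along the minor axis
    shrink_major = rho / sin_major
    new_major = d_major - 2 * shrink_major
    new_minor = d_minor - 2 * shrink_minor
    if new_major <= 0 or new_minor <= 0:
        raise InvalidGeometryError(
            f"fillet radius {rho} too large for diamond {d_major}x{d_minor}"
        )
    return _diamond(center, new_major, new_minor), shrink_minor


def _rounded_boundary(inset_poly: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Sample points on the offset surface {dist(inset_poly) = rho}."""
    ts = np.linspace(0, 1, max(n // 8, 4), endpoint=False)
    pts = []
    m = len(inset_poly)
    for i in range(m):
        a, b = inset_poly[i], inset_poly[(i + 1) % m]
        e = b - a
        nrm = np.array([e[1], -e[0]])
        nrm = nrm / np.linalg.norm(nrm)
        # ensure outward normal (away from polygon centroid)
        if np.dot(nrm, a - inset_poly.mean(axis=0)) < 0:
            nrm = -nrm
        seg = a + ts[:, None] * e
        pts.append(seg + rho * nrm)
        # vertex arc
        ang = np.linspace(0, 2 * np.pi, max(n // 8, 8), endpoint=False)
        circle = a + rho * np.column_stack([np.cos(ang), np.sin(ang)])
        d, _ = polygon_signed_distance(circle, inset_poly)
        pts.append(circle[d > rho * 0.999])
    return np.vstack(pts)


def _prism_triangulation(inset_poly, rho, height, n_boundary=64):
    """Triangulated side wall of one rounded prism (for export/inspection)."""
    ring = _rounded_boundary(inset_poly, rho, n_boundary) if rho > 0 else inset_poly
    # order the ring by angle around its centroid
    c = ring.mean(axis=0)
    order = np.argsort(np.arctan2(ring[:, 1] - c[1], ring[:, 0] - c[0]))
    ring = ring[order]
    m = len(ring)
    lower = np.column_stack([ring, np.zeros(m)])
    upper = np.column_stack([ring, np.full(m, height)])
    pts = np.vstack([lower, upper])
    tris = []
    for i in range(m):
        j = (i + 1) % m
        tris.append([i, j, m + i])
        tris.append([j, m + j, m + i])
    return pts, np.asarray(tris)


def build_pillar_surface(geometry: TrapGeometry) -> RigidSurface:
    """Construct the rigid pillar pair for one trapping unit.

    The facing (minor-diagonal) vertices are rounded with the fillet radius;
    centres are offset so that the minimum clearance between the rounded
    surfaces equals ``geometry.gap`` exactly.  The gap throat plane is x = 0.
    """
    g = geometry
    rho = g.fillet_radius
    if rho > 0:
        _, shrink_minor = _inset_diamond(
            np.zeros(2), g.diagonal_major, g.diagonal_minor, rho
        )
    else:
        shrink_minor = 0.0
    # rounded tip sits at |y| = center_offset - (d_minor/2 - shrink + rho)
    tip_extent = g.diagonal_minor / 2 - shrink_minor + rho
    yc = g.gap / 2 + tip_extent
    polys = []
    for sign in (+1, -1):
        center = np.array([0.0, sign * yc])
        if rho > 0:
            poly, _ = _inset_diamond(center, g.diagonal_major, g.diagonal_minor, rho)
        else:
            poly = _diamond(center, g.diagonal_major, g.diagonal_minor)
        polys.append(poly)

    pts_list, tri_list = [], []
    offset = 0
    for poly in polys:
        pts, tris = _prism_triangulation(poly, rho, g.height)
        pts_list.append(pts)
        tri_list.append(tris + offset)
        offset += len(pts)
    return RigidSurface(
        geometry=g,
        inset_polys=(polys[0], polys[1]),
        fillet=rho,
        gap_throat_plane=0.0,
        points=np.vstack(pts_list),
        triangles=np.vstack(tri_list),
    )
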