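"""Parabolic hydrodynamic loading of the cell.

The carrier flow pushes the cell against the trap with a pressure that is
maximal on the flow axis and falls off towards the cell rim.  It is modelled
as the axisymmetric parabolic field

    p(y, z) = P0 * f(y, z),   f(y, z) = 1 - (y^2 + z^2) / r^2

acting along the flow axis (+x) on the upstream ("front") part of the cell
surface, with r the cell radius and (y, z) measured from the instantaneous
cell centroid so the load travels with the cell.  Points outside the disk
y^2 + z^2 > r^2 take factor 0 (clamped, logged once).

The resultant of the full load over the disk is P0 * pi * r^2 / 2 in closed
form — a convenient check against any numerical quadrature.

The front region is the upstream hemisphere: surface locations with
x <= centroid x.  Tractions point along the fixed +x flow axis
(non-follower load).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = ["ParabolicLoad", "field_factor", "apply_traction", "resultant_force",
           "nodal_forces"]


@dataclass(frozen=True)
class ParabolicLoad:
    """Peak pressure ``magnitude`` (Pa, P0), ``cell_radius`` r (um), and the
    unit flow ``direction`` (default +x)."""

    magnitude: float
    cell_radius: float
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if self.magnitude < 0:
            raise InvalidInputError(f"magnitude must be >= 0, got {self.magnitude}")
        if not self.cell_radius > 0:
            raise InvalidInputError(
                f"cell_radius must be > 0, got {self.cell_radius}"
            )
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3,) or not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise InvalidInputError("direction must be a 3-vector of unit length")
        object.__setattr__(self, "direction", tuple(d))


def field_factor(load: ParabolicLoad, y, z):
    """Dimensionless factor f(y, z) = 1 - (y^2 + z^2)/r^2, clamped to 0
    outside the loaded disk.  Vectorized over y, z."""
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    f = 1.0 - (y**2 + z**2) / load.cell_radius**2
    clipped = f < 0
    if np.any(clipped):
        logger.debug("%d point(s) outside the loaded disk, factor clamped to 0",
                     int(np.count_nonzero(clipped)))
    return np.where(clipped, 0.0, f)


def resultant_force(load: ParabolicLoad) -> float:
    """Closed-form resultant of the parabolic load over its disk:
    P0 * pi * r^2 / 2, in pN (Pa * um^2)."""
    return load.magnitude * np.pi * load.cell_radius**2 / 2.0


def apply_traction(
    load: ParabolicLoad,
    surface_points: np.ndarray,
    front_region: str = "upstream-hemisphere",
) -> np.ndarray:
    """Per-point traction vectors (Pa) at the given surface points.

    Points are taken in the cell frame.  With the default selection rule the
    upstream hemisphere — points with x <= the centroid x of all points —
    receives traction P0 * f(y, z) along the flow direction; the rest
    receives zero.  ``front_region="all"`` loads every point in the disk.
    """
    pts = np.asarray(surface_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidInputError("surface_points must have shape (n, 3)")
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    if front_region == "upstream-hemisphere":
        selected = rel[:, 0] <= 0.0
    elif front_region == "all":
        selected = np.ones(len(pts), dtype=bool)
    else:
        raise InvalidInputError(f"unknown front_region rule {front_region!r}")
    if not np.any(selected):
        logger.warning("front-region selection is empty; applying zero load")
    f = field_factor(load, rel[:, 1], rel[:, 2])
    mag = np.where(selected, load.magnitude * f, 0.0)
    return mag[:, None] * np.asarray(load.direction)


def nodal_forces(
    load: ParabolicLoad,
    points: np.ndarray,
    triangles: np.ndarray,
    centroid: np.ndarray | None = None,
) -> np.ndarray:
    """Consistent (one-point-quadrature) nodal forces (pN) for the parabolic
    load on a triangulated cell surface.

    The load is a pressure acting along the flow axis: each upstream
    triangle — centroid x at or behind the body centroid x — contributes
    P0 * f(y, z) times its flow-projected area (|n_x| A), split equally
    among its three nodes, so the resultant over a hemisphere equals the
    disk integral P0 * pi * r^2 / 2.  Areas are those of the deformed
    surface passed in.
    """
    pts = np.asarray(points, dtype=float)
    tris = np.asarray(triangles, dtype=int)
    body_c = pts.mean(axis=0) if centroid is None else np.asarray(centroid, float)
    p0, p1, p2 = pts[tris[:, 0]], pts[tris[:, 1]], pts[tris[:, 2]]
    tc = (p0 + p1 + p2) / 3.0
    areas = 0.5 * np.abs(np.cross(p1 - p0, p2 - p0)[:, 0])
    rel = tc - body_c
    sel = rel[:, 0] <= 0.0
    f = field_factor(load, rel[:, 1], rel[:, 2])
    tri_force = (load.magnitude * f * areas * sel)[:, None] * np.asarray(
        load.direction
    )
    out = np.zeros_like(pts)
    for k in range(3):
        np.add.at(out, tris[:, k], tri_force / 3.0)
    return out
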