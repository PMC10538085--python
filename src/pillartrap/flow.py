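"""Steady laminar carrier flow through the trapping unit.

Solves the steady incompressible momentum/continuity system

    rho (u . grad) u = div( -p I + mu (L + L^T) ),    div u = 0

on a 2D plan-view domain, depth-averaged over the channel height h by a
Brinkman-type drag term  -12 mu / h^2 * u  (Hele-Shaw closure; a flag
disables it for pure 2D Stokes).  At device scale the Reynolds number is
O(1e-2), so the convective term — retained and handled by Picard
iteration — is a small correction and the solution is near-linear in the
flow rate Q.

Discretization: staggered (MAC) finite volumes on a graded rectilinear
grid; u at vertical faces, v at horizontal faces, p at cell centres; solid
pillars enter as masked cells whose faces carry no-slip Dirichlet values.
Discrete continuity is enforced exactly in every fluid cell by a direct
sparse solve of the saddle-point system, so inlet and outlet volumetric
fluxes balance to solver precision.

Boundary conditions: uniform inlet velocity u = Q / (W h) at x = x_min,
zero-pressure outlet at x = x_max, and either no-slip walls or symmetry
(slip) lines at the lateral boundaries.  The symmetry option models one
unit cell of an infinite pillar row: the domain spans gap centreline to
pillar centreline mirror, and all flow passes through the gap.

Units: geometry in um, Q in uL/min; fields are stored in SI (m/s, Pa).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConvergenceError, InvalidInputError, MeshError
from .types import TrapGeometry
from .contact.pillars import build_pillar_surface

logger = logging.getLogger(__name__)

__all__ = [
    "FlowConditions",
    "FlowDomain",
    "FlowSolution",
    "straight_channel_domain",
    "trapping_unit_domain",
    "solve_flow",
    "pressure_along_gap",
    "gap_mean_pressure",
    "cross_gap_velocity",
]

_UL_PER_MIN = 1e-9 / 60.0  # uL/min -> m^3/s
_UM = 1e-6


@dataclass(frozen=True)
class FlowConditions:
    """Fluid and operating parameters.

    density kg/m^3; viscosity Pa.s; flow_rate uL/min; channel height and
    width um.  ``channel_width`` is the full width over which the pump's
    flow rate is distributed — for a trapping-unit domain that is the
    chamber width spanned by the whole pillar row (default 2 mm), not the
    width of the single simulated unit cell; the inlet velocity
    Q / (width x height) is what the unit cell sees.  The Reynolds number
    is logged at solve time.
    """

    flow_rate: float
    density: float = 1000.0
    viscosity: float = 1.0e-3
    channel_height: float = 50.0
    channel_width: float = 2000.0

    def __post_init__(self):
        for name in ("density", "viscosity", "channel_height", "channel_width"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be > 0")
        if self.flow_rate < 0:
            raise InvalidInputError("flow_rate must be >= 0")

    @property
    def flow_rate_si(self) -> float:
        return self.flow_rate * _UL_PER_MIN


@dataclass(frozen=True)
class FlowDomain:
    """Plan-view rectangular domain [x0, x1] x [y0, y1] (um) with a solid
    mask on a graded rectilinear grid.

    xf, yf     cell-face coordinates (um), lengths nx+1 / ny+1
    solid      (nx, ny) bool, True inside a pillar
    wall_type  "noslip" or "symmetry" for the two lateral boundaries
    """

    xf: np.ndarray
    yf: np.ndarray
    solid: np.ndarray
    wall_type: str = "noslip"
    geometry: TrapGeometry | None = None

    def __post_init__(self):
        if self.wall_type not in ("noslip", "symmetry"):
            raise InvalidInputError("wall_type must be 'noslip' or 'symmetry'")
        if self.solid.shape != (len(self.xf) - 1, len(self.yf) - 1):
            raise MeshError("solid mask does not match the grid")
        if np.any(np.diff(self.xf) <= 0) or np.any(np.diff(self.yf) <= 0):
            raise MeshError("face coordinates must be strictly increasing")
        # inlet column must be fully fluid, else the uniform inlet is invalid
        if np.any(self.solid[0, :]) or np.any(self.solid[-1, :]):
            raise MeshError("inlet/outlet columns must be free of solid cells")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.xf) - 1, len(self.yf) - 1

    @property
    def xc(self) -> np.ndarray:
        return 0.5 * (self.xf[:-1] + self.xf[1:])

    @property
    def yc(self) -> np.ndarray:
        return 0.5 * (self.yf[:-1] + self.yf[1:])

    @property
    def width(self) -> float:
        return float(self.yf[-1] - self.yf[0])


@dataclass
class FlowSolution:
    """Converged fields on the staggered grid: u (nx+1, ny) and v (nx, ny+1)
    in m/s, p (nx, ny) in Pa; plus conservation diagnostics."""

    domain: FlowDomain
    conditions: FlowConditions
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    converged: bool
    picard_iterations: int
    max_divergence: float  # m^3/s per cell, after solve

    def inlet_flux(self) -> float:
        """Volumetric flux through the inlet, m^3/s."""
        dy = np.diff(self.domain.yf) * _UM
        h = self.conditions.channel_height * _UM
        return float(np.sum(self.u[0, :] * dy) * h)

    def outlet_flux(self) -> float:
        dy = np.diff(self.domain.yf) * _UM
        h = self.conditions.channel_height * _UM
        return float(np.sum(self.u[-1, :] * dy) * h)

    def pressure_at(self, points_xy: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of cell-centre pressure at (x, y) um."""
        from scipy.interpolate import RegularGridInterpolator

        dom = self.domain
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
        if (
            pts[:, 0].min() < dom.xf[0] or pts[:, 0].max() > dom.xf[-1]
            or pts[:, 1].min() < dom.yf[0] or pts[:, 1].max() > dom.yf[-1]
        ):
            raise InvalidInputError("query points outside the flow domain")
        interp = RegularGridInterpolator(
            (dom.xc, dom.yc), self.p, bounds_error=False, fill_value=None
        )
        return interp(pts)


# ---------------------------------------------------------------------------
# domain builders


def _graded(start: float, stop: float, fine_lo: float, fine_hi: float,
            d_fine: float, ratio: float = 1.2, d_max: float = 5.0) -> np.ndarray:
    """Face coordinates from start to stop with spacing d_fine inside
    [fine_lo, fine_hi], geometrically stretched outside."""

    def stretch(a, b, d0, sign):
        # from a towards b with growing spacing
        pts = [a]
        d = d0
        while (b - pts[-1]) * sign > 1e-9:
            d = min(d * ratio, d_max)
            nxt = pts[-1] + sign * d
            if (b - nxt) * sign < d0 * 0.5:
                break
            pts.append(nxt)
        return pts

    core = list(np.arange(fine_lo, fine_hi + d_fine * 0.5, d_fine))
    left = stretch(fine_lo, start, d_fine, -1.0)[1:]
    right = stretch(fine_hi, stop, d_fine, +1.0)[1:]
    faces = np.array(sorted(set([start, stop] + core + left + right)))
    return _merge_close(faces, 0.25 * d_fine)


def _merge_close(faces: np.ndarray, tol: float) -> np.ndarray:
    """Drop faces closer than tol to their predecessor (endpoints kept)."""
    keep = [faces[0]]
    for f in faces[1:-1]:
        if f - keep[-1] > tol:
            keep.append(f)
    if faces[-1] - keep[-1] <= tol:
        keep.pop()
    keep.append(faces[-1])
    return np.array(keep)


def straight_channel_domain(
    length: float, width: float, d_fine: float | None = None,
    wall_type: str = "noslip",
) -> FlowDomain:
    """Obstacle-free rectangular channel, the Poiseuille benchmark case."""
    dx = d_fine or length / 50.0
    dyw = min(width / 16.0, 8.0)
    xf = np.linspace(0.0, length, max(int(length / dx), 10) + 1)
    # refine near the lateral walls where the Brinkman boundary layer lives
    yf = _graded(0.0, width, 0.0, width, dyw, d_max=dyw)
    # add extra-fine wall bands
    band = np.concatenate([
        np.arange(0.0, min(20.0, width / 4), 1.0),
        width - np.arange(0.0, min(20.0, width / 4), 1.0),
    ])
    yf = _merge_close(
        np.array(sorted(set(np.concatenate([yf, band]).round(9)))), dyw / 16
    )
    solid = np.zeros((len(xf) - 1, len(yf) - 1), dtype=bool)
    return FlowDomain(xf=xf, yf=yf, solid=solid, wall_type=wall_type)


def trapping_unit_domain(
    geometry: TrapGeometry,
    length: float | None = None,
    resolution: float | None = None,
) -> FlowDomain:
    """One unit cell of an infinite pillar row.

    The domain spans the gap centreline to the mirror plane through the
    pillar centre on each side (total width gap + minor diagonal), with
    symmetry (slip) lateral boundaries, so the whole flux crosses the gap.
    The gap region is meshed at ~1/10 of the gap size.
    """
    g = geometry
    half_len = length / 2 if length else 1.5 * g.diagonal_major
    d_fine = resolution or g.gap / 10.0
    w_half = (g.gap + g.diagonal_minor) / 2.0
    xf = _graded(-half_len, half_len, -g.diagonal_major / 2 - 2, g.diagonal_major / 2 + 2,
                 d_fine, d_max=6.0)
    # y-grid: exact faces at +/- gap/2, fine through the gap band
    yf = _graded(-w_half, w_half, -g.gap / 2, g.gap / 2, d_fine, d_max=4.0)
    surface = build_pillar_surface(g)
    xc = 0.5 * (xf[:-1] + xf[1:])
    yc = 0.5 * (yf[:-1] + yf[1:])
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    sdf = surface.signed_distance(pts).reshape(X.shape)
    solid = sdf < 0.0
    return FlowDomain(xf=xf, yf=yf, solid=solid, wall_type="symmetry",
                      geometry=g)


# ---------------------------------------------------------------------------
# solver


def solve_flow(
    domain: FlowDomain,
    conditions: FlowConditions,
    include_convection: bool = True,
    brinkman: bool = True,
    max_picard: int = 6,
    picard_tol: float = 1e-8,
) -> FlowSolution:
    """Solve the steady depth-averaged flow on ``domain``.

    Returns a converged :class:`FlowSolution`; raises
    :class:`ConvergenceError` with the residual history if the Picard loop
    does not settle.
    """
    nx, ny = domain.shape
    xf = domain.xf * _UM
    yf = domain.yf * _UM
    dx = np.diff(xf)
    dy = np.diff(yf)
    mu = conditions.viscosity
    rho = conditions.density
    h = conditions.channel_height * _UM
    alpha = 12.0 * mu / h**2 if brinkman else 0.0

    width = conditions.channel_width * _UM
    u_in = conditions.flow_rate_si / (width * h)
    re = rho * u_in * min(width, h) / mu
    logger.info("inlet velocity %.3g m/s, Reynolds number %.3g", u_in, re)

    solid = domain.solid
    # staggered unknowns
    n_u = (nx + 1) * ny
    n_v = nx * (ny + 1)
    n_p = nx * ny

    def iu(i, j):
        return i * ny + j

    def iv(i, j):
        return n_u + i * (ny + 1) + j

    def ip(i, j):
        return n_u + n_v + i * ny + j

    # face classifications
    u_dirichlet = np.zeros((nx + 1, ny))  # value
    u_is_dir = np.zeros((nx + 1, ny), dtype=bool)
    u_is_dir[0, :] = True
    u_dirichlet[0, :] = u_in
    for i in range(1, nx + 1):
        for j in range(ny):
            left_solid = solid[i - 1, j] if i - 1 >= 0 else False
            right_solid = solid[i, j] if i < nx else False
            if left_solid or right_solid:
                u_is_dir[i, j] = True

    v_is_dir = np.zeros((nx, ny + 1), dtype=bool)
    v_is_dir[:, 0] = True
    v_is_dir[:, ny] = True
    for i in range(nx):
        for j in range(1, ny):
            if solid[i, j - 1] or solid[i, j]:
                v_is_dir[i, j] = True

    noslip = domain.wall_type == "noslip"

    def assemble():
        """Linear operator and constant RHS (convection enters the RHS
        separately, so A is assembled and factorized once)."""
        rows, cols, vals = [], [], []

        def add(r, c, v):
            rows.append(r)
            cols.append(c)
            vals.append(v)

        b = np.zeros(n_u + n_v + n_p)

        # --- u momentum ---------------------------------------------------
        for i in range(nx + 1):
            for j in range(ny):
                row = iu(i, j)
                if u_is_dir[i, j]:
                    add(row, row, 1.0)
                    b[row] = u_dirichlet[i, j]
                    continue
                dxc = 0.5 * (dx[i - 1] + dx[i]) if 0 < i < nx else dx[min(i, nx - 1)]
                diag = alpha
                # d/dx(mu du/dx): neighbours at i-1, i+1 across cells
                if i > 0:
                    tw = mu / dx[i - 1] / dxc
                    if u_is_dir[i - 1, j]:
                        b[row] += tw * u_dirichlet[i - 1, j]
                    else:
                        add(row, iu(i - 1, j), -tw)
                    diag += tw
                if i < nx:
                    te = mu / dx[i] / dxc
                    if u_is_dir[i + 1, j]:
                        b[row] += te * u_dirichlet[i + 1, j]
                    else:
                        add(row, iu(i + 1, j), -te)
                    diag += te
                # else: outlet face, zero-gradient ghost, no east viscous term
                # d/dy(mu du/dy)
                if j > 0:
                    dyc = 0.5 * (dy[j - 1] + dy[j])
                    ts = mu / dyc / dy[j]
                    if u_is_dir[i, j - 1]:
                        b[row] += ts * u_dirichlet[i, j - 1]
                    else:
                        add(row, iu(i, j - 1), -ts)
                    diag += ts
                elif noslip:
                    diag += 2.0 * mu / dy[j] / dy[j]  # ghost = -u
                if j < ny - 1:
                    dyc = 0.5 * (dy[j] + dy[j + 1])
                    tn = mu / dyc / dy[j]
                    if u_is_dir[i, j + 1]:
                        b[row] += tn * u_dirichlet[i, j + 1]
                    else:
                        add(row, iu(i, j + 1), -tn)
                    diag += tn
                elif noslip:
                    diag += 2.0 * mu / dy[j] / dy[j]
                # pressure gradient
                if i == nx:
                    # outlet: p ghost = 0 at the boundary
                    add(row, ip(nx - 1, j), -1.0 / (0.5 * dx[nx - 1]))
                else:
                    add(row, ip(i, j), 1.0 / dxc)
                    add(row, ip(i - 1, j), -1.0 / dxc)
                add(row, row, diag)

        # --- v momentum ---------------------------------------------------
        for i in range(nx):
            for j in range(ny + 1):
                row = iv(i, j)
                if v_is_dir[i, j]:
                    add(row, row, 1.0)
                    continue
                dyc = 0.5 * (dy[j - 1] + dy[j])
                diag = alpha
                if j > 0:
                    ts = mu / dy[j - 1] / dyc
                    if not v_is_dir[i, j - 1]:
                        add(row, iv(i, j - 1), -ts)
                    diag += ts
                if j < ny:
                    tn = mu / dy[j] / dyc
                    if not v_is_dir[i, j + 1]:
                        add(row, iv(i, j + 1), -tn)
                    diag += tn
                if i > 0:
                    dxc = 0.5 * (dx[i - 1] + dx[i])
                    tw = mu / dxc / dx[i]
                    if not v_is_dir[i - 1, j]:
                        add(row, iv(i - 1, j), -tw)
                    diag += tw
                else:
                    # inlet: v = 0 ghost (uniform axial inflow)
                    diag += 2.0 * mu / dx[i] / dx[i]
                if i < nx - 1:
                    dxc = 0.5 * (dx[i] + dx[i + 1])
                    te = mu / dxc / dx[i]
                    if not v_is_dir[i + 1, j]:
                        add(row, iv(i + 1, j), -te)
                    diag += te
                # else: outlet zero-gradient ghost
                add(row, ip(i, j), 1.0 / dyc)
                add(row, ip(i, j - 1), -1.0 / dyc)
                add(row, row, diag)

        # --- continuity -----------------------------------------------------
        for i in range(nx):
            for j in range(ny):
                row = ip(i, j)
                if solid[i, j]:
                    add(row, row, 1.0)
                    continue
                # per-unit-volume form (divergence, 1/s) keeps the row scale
                # comparable to the momentum rows
                for col, coef, is_dir, val in (
                    (iu(i + 1, j), 1.0 / dx[i], u_is_dir[i + 1, j], u_dirichlet[i + 1, j]),
                    (iu(i, j), -1.0 / dx[i], u_is_dir[i, j], u_dirichlet[i, j]),
                    (iv(i, j + 1), 1.0 / dy[j], v_is_dir[i, j + 1], 0.0),
                    (iv(i, j), -1.0 / dy[j], v_is_dir[i, j], 0.0),
                ):
                    if is_dir:
                        b[row] -= coef * val
                    else:
                        add(row, col, coef)
        n_tot = n_u + n_v + n_p
        A = sp.coo_matrix((vals, (rows, cols)), shape=(n_tot, n_tot)).tocsc()
        return A, b

    def convection_rhs(u_prev, v_prev):
        """First-order-upwind rho (U.grad)U at u and v faces, vectorized."""
        b = np.zeros(n_u + n_v + n_p)
        # u faces
        dudx_b = np.zeros_like(u_prev)
        dudx_b[1:, :] = (u_prev[1:, :] - u_prev[:-1, :]) / dx[:, None]
        dudx_f = np.zeros_like(u_prev)
        dudx_f[:-1, :] = (u_prev[1:, :] - u_prev[:-1, :]) / dx[:, None]
        dudx = np.where(u_prev >= 0, dudx_b, dudx_f)
        il = np.clip(np.arange(nx + 1) - 1, 0, nx - 1)
        ir = np.clip(np.arange(nx + 1), 0, nx - 1)
        vc = 0.25 * (
            v_prev[ir][:, :-1] + v_prev[ir][:, 1:]
            + v_prev[il][:, :-1] + v_prev[il][:, 1:]
        )
        dudy_b = np.zeros_like(u_prev)
        dudy_b[:, 1:] = (u_prev[:, 1:] - u_prev[:, :-1]) / dy[None, 1:]
        dudy_f = np.zeros_like(u_prev)
        dudy_f[:, :-1] = (u_prev[:, 1:] - u_prev[:, :-1]) / dy[None, :-1]
        dudy = np.where(vc >= 0, dudy_b, dudy_f)
        conv_u = -rho * (u_prev * dudx + vc * dudy)
        conv_u[u_is_dir] = 0.0
        b[:n_u] = conv_u.ravel()
        # v faces
        jm = np.clip(np.arange(ny + 1) - 1, 0, ny - 1)
        jp = np.clip(np.arange(ny + 1), 0, ny - 1)
        uc = 0.25 * (
            u_prev[:-1][:, jm] + u_prev[1:][:, jm]
            + u_prev[:-1][:, jp] + u_prev[1:][:, jp]
        )
        dvdx_b = np.zeros_like(v_prev)
        dvdx_b[1:, :] = (v_prev[1:, :] - v_prev[:-1, :]) / dx[1:, None]
        dvdx_f = np.zeros_like(v_prev)
        dvdx_f[:-1, :] = (v_prev[1:, :] - v_prev[:-1, :]) / dx[:-1, None]
        dvdx = np.where(uc >= 0, dvdx_b, dvdx_f)
        dvdy_b = np.zeros_like(v_prev)
        dvdy_b[:, 1:-1] = (v_prev[:, 1:-1] - v_prev[:, :-2]) / dy[None, :-1]
        dvdy_f = np.zeros_like(v_prev)
        dvdy_f[:, 1:-1] = (v_prev[:, 2:] - v_prev[:, 1:-1]) / dy[None, 1:]
        dvdy = np.where(v_prev >= 0, dvdy_b, dvdy_f)
        conv_v = -rho * (uc * dvdx + v_prev * dvdy)
        conv_v[v_is_dir] = 0.0
        b[n_u:n_u + n_v] = conv_v.ravel()
        return b

    A, b0 = assemble()
    lu = spla.splu(A)
    u = np.zeros((nx + 1, ny))
    v = np.zeros((nx, ny + 1))
    p = np.zeros((nx, ny))
    history = []
    iterations = 0
    for it in range(max_picard if include_convection else 1):
        iterations = it + 1
        b = b0.copy()
        if include_convection and it > 0:
            b += convection_rhs(u, v)
        sol = lu.solve(b)
        u_new = sol[:n_u].reshape(nx + 1, ny)
        v_new = sol[n_u:n_u + n_v].reshape(nx, ny + 1)
        p = sol[n_u + n_v:].reshape(nx, ny)
        scale = max(np.abs(u_new).max(), 1e-300)
        delta = max(np.abs(u_new - u).max(), np.abs(v_new - v).max()) / scale
        history.append(delta)
        u, v = u_new, v_new
        if not include_convection or (it > 0 and delta < picard_tol):
            break
    else:
        if include_convection and history[-1] > 1e-3:
            raise ConvergenceError("Picard iteration did not converge", history)
        logger.info("Picard residual %.2e after %d iterations", history[-1], iterations)

    # divergence diagnostic
    du = (u[1:, :] - u[:-1, :]) * dy[None, :]
    dv = (v[:, 1:] - v[:, :-1]) * dx[:, None]
    div = np.where(solid, 0.0, du + dv)
    return FlowSolution(
        domain=domain,
        conditions=conditions,
        u=u,
        v=v,
        p=p,
        converged=True,
        picard_iterations=iterations,
        max_divergence=float(np.abs(div).max() * h),
    )


# ---------------------------------------------------------------------------
# post-processing


def pressure_along_gap(solution: FlowSolution, path_xy: np.ndarray | None = None,
                       n_samples: int = 200):
    """Pressure vs arc length (um, Pa) along a polyline through the gap.

    Default path: the x-axis (gap centreline) across the pillar extent.
    """
    dom = solution.domain
    if path_xy is None:
        g = dom.geometry
        half = (g.diagonal_major / 2 + 10.0) if g else (dom.xf[-1] - dom.xf[0]) / 4
        path_xy = np.column_stack([np.linspace(-half, half, n_samples),
                                   np.zeros(n_samples)])
    path_xy = np.atleast_2d(np.asarray(path_xy, dtype=float))
    seg = np.linalg.norm(np.diff(path_xy, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    pressure = solution.pressure_at(path_xy)
    return arc, np.asarray(pressure)


def gap_mean_pressure(solution: FlowSolution, geometry: TrapGeometry | None = None) -> float:
    """Mean pressure difference (Pa) across the gap region: cross-section
    average just upstream of the pillars minus just downstream.  This is the
    suggested peak magnitude P0 for the mechanical load."""
    dom = solution.domain
    g = geometry or dom.geometry
    x_half = (g.diagonal_major / 2 + 2.0) if g else (dom.xf[-1] - dom.xf[0]) / 4
    out = []
    for x_q in (-x_half, x_half):
        i = int(np.argmin(np.abs(dom.xc - x_q)))
        fluid = ~dom.solid[i, :]
        w = np.diff(dom.yf)[fluid]
        out.append(float(np.sum(solution.p[i, fluid] * w) / np.sum(w)))
    return out[0] - out[1]


def cross_gap_velocity(solution: FlowSolution, x: float = 0.0):
    """(y um, u m/s) samples of the axial velocity across the gap at the
    given x (default: the throat), restricted to fluid cells."""
    dom = solution.domain
    i = int(np.argmin(np.abs(dom.xf - x)))
    ic = min(i, dom.shape[0] - 1)
    fluid = ~dom.solid[ic, :]
    return dom.yc[fluid], solution.u[i, fluid]
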