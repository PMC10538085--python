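"""Quasi-static passage simulation and critical-pressure search.

A neo-Hookean sphere is pushed by the parabolic pressure field against the
rigid pillar pair.  Each load increment minimizes the total potential

    Pi(x) = elastic(x) + contact_penalty(x) - f . x + (eta/2) sum_i w_i |x_i - x_i^prev|^2

with L-BFGS.  The last term is pseudo-time damping: a free body under a
pressure load has no static equilibrium until contact balances the load, so
the damping caps the advance per increment (at ``step_cap`` cell radii) and
turns rigid-body drift into a controlled march.  After the load ramp the
increments continue at constant load until either the centroid passes the
gap throat by one cell radius (escape) or the configuration stops changing
(trapped equilibrium).

Contact is a frictionless penalty on the signed distance of surface nodes to
the rounded pillars; the penalty stiffness starts at
``penalty_factor * E / edge`` and is escalated x4 whenever the residual
penetration exceeds the tolerance (1% of the gap by default).

The solver works in dimensionless variables (lengths / cell radius,
stresses / E).  Consequently the outcome depends only on shape ratios and on
P0/E: critical pressure is exactly linear in the cell modulus and invariant
under joint geometric rescaling, as it is for the continuum problem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from ..errors import ConvergenceError, InconsistentOutcomeError, MeshError
from ..loading import ParabolicLoad, nodal_forces
from ..types import CellSpec, SweepRecord, TrapGeometry
from .hyperelastic import ElementKernel, MaterialNH
from .mesh import CellMesh, build_cell_mesh, tet_volumes
from .pillars import RigidSurface, build_pillar_surface

logger = logging.getLogger(__name__)

__all__ = [
    "SolverOptions",
    "SimOutcome",
    "CriticalPressureResult",
    "simulate_passage",
    "find_critical_pressure",
    "sweep",
    "clear_cache",
]


@dataclass(frozen=True)
class SolverOptions:
    """Numerical knobs of the passage solver (dimensionless unless noted).

    mesh_resolution     lattice divisions of the cell mesh (4 => 384 tets)
    n_ramp              increments over which the load ramps 0 -> P0
    budget              total increment budget
    step_cap            max free advance per increment, in cell radii
    disp_tol            stall threshold on nodal displacement, in cell radii
    penalty_factor      contact stiffness = penalty_factor * E / edge length
    penetration_tol     allowed residual penetration, as a fraction of gap
    max_iter            L-BFGS iterations per increment
    """

    mesh_resolution: int = 4
    n_ramp: int = 8
    budget: int = 160
    step_cap: float = 0.35
    disp_tol: float = 5e-4
    penalty_factor: float = 100.0
    penetration_tol: float = 0.01
    max_iter: int = 200
    max_penalty_escalations: int = 3
    patience: int = 20  # increments without forward progress => trapped

    def fingerprint(self) -> tuple:
        return (
            self.mesh_resolution,
            self.n_ramp,
            self.budget,
            self.step_cap,
            self.disp_tol,
            self.penalty_factor,
            self.penetration_tol,
            self.max_iter,
            self.patience,
        )


@dataclass
class SimOutcome:
    """Result of one passage simulation at fixed peak pressure."""

    escaped: bool
    centroid_path: np.ndarray  # centroid x (um) per accepted increment
    max_principal_stretch: float
    converged: bool
    max_penetration: float  # um
    increments: int
    final_nodes: np.ndarray | None = None  # um, for export


@dataclass(frozen=True)
class CriticalPressureResult:
    """Bisection estimate of the escape threshold.

    pc is the lowest pressure observed to produce escape (the upper bracket
    end); the true threshold lies in (bracket[0], pc]."""

    pc: float
    bracket: tuple[float, float]
    iterations: int
    tolerance: float


def build_pillars(geometry: TrapGeometry) -> RigidSurface:
    return build_pillar_surface(geometry)


def _scaled_surface_sdf(surface: RigidSurface, radius: float):
    """Dimensionless signed distance + gradient closure (lengths / radius)."""

    def sdf_grad(p_hat_xy):
        d, g = surface.signed_distance_grad(np.asarray(p_hat_xy) * radius)
        return d / radius, g

    return sdf_grad


def _initial_center_x(radius: float, surface: RigidSurface, clearance: float):
    """x of the sphere centre so that it sits just upstream of the pillars
    (touching within ``clearance``), or a free-stream position when the
    sphere fits through the gap."""
    theta = np.linspace(0, 2 * np.pi, 128, endpoint=False)
    circle = radius * np.column_stack([np.cos(theta), np.sin(theta)])

    def min_sdf(xc):
        pts = circle + np.array([xc, 0.0])
        return float(np.min(surface.signed_distance(pts)))

    if min_sdf(0.0) > clearance:  # free passage, start just upstream
        return -1.25 * radius
    x_far = -(surface.geometry.diagonal_major / 2 + radius + surface.geometry.gap)
    # xtol scales with the radius so placement is exactly scale-covariant
    return optimize.brentq(
        lambda x: min_sdf(x) - clearance, x_far, 0.0, xtol=1e-9 * radius
    )


def _surface_node_areas(nodes, tris, node_ids):
    p0, p1, p2 = nodes[tris[:, 0]], nodes[tris[:, 1]], nodes[tris[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)
    acc = np.zeros(len(nodes))
    for k in range(3):
        np.add.at(acc, tris[:, k], areas / 3.0)
    return acc[node_ids]


def simulate_passage(
    mesh: CellMesh,
    material: MaterialNH,
    surface: RigidSurface,
    load: ParabolicLoad,
    options: SolverOptions = SolverOptions(),
    x_offset: float | None = None,
    initial_nodes: np.ndarray | None = None,
) -> SimOutcome:
    """Advance the damped quasi-static solution and classify the outcome.

    ``mesh`` is a cell mesh centred at the origin; it is translated to
    ``x_offset`` (default: touching the pillars upstream) before loading.
    ``load.magnitude`` is the peak pressure P0 in Pa.

    ``initial_nodes`` (physical um) warm-starts the run from a previously
    computed deformed state — used for pressure continuation, where each
    probe starts from the equilibrium found at the last lower pressure; the
    load ramp is skipped in that case.  The stress-free reference is always
    the undeformed sphere.
    """
    opts = options
    E = material.source_modulus
    nu = material.source_poisson
    radius = load.cell_radius
    p_star = load.magnitude / E
    warm = initial_nodes is not None

    # --- dimensionless setup -------------------------------------------------
    if x_offset is None:
        x_offset = _initial_center_x(radius, surface, 0.02 * radius)
    nodes0 = mesh.nodes / radius + np.array([x_offset / radius, 0.0, 0.0])
    kernel = ElementKernel(
        nodes0,
        mesh.elements,
        c10=1.0 / (4.0 * (1.0 + nu)),
        kappa_d1=1.0 / (6.0 * (1.0 - 2.0 * nu)),
    )
    node_w = np.zeros(len(nodes0))  # lumped nodal volumes (damping weights)
    vols = tet_volumes(nodes0, mesh.elements)
    for k in range(4):
        np.add.at(node_w, mesh.elements[:, k], vols / 4.0)

    surf_ids = np.unique(mesh.surface)
    sdf_grad = _scaled_surface_sdf(surface, radius)
    throat_hat = surface.gap_throat_plane / radius
    gap_hat = surface.geometry.gap / radius
    pen_tol_hat = opts.penetration_tol * gap_hat

    edge_hat = float(
        np.mean(
            np.linalg.norm(
                nodes0[mesh.surface[:, 0]] - nodes0[mesh.surface[:, 1]], axis=1
            )
        )
    )
    k_pen = opts.penalty_factor / edge_hat

    load_hat = ParabolicLoad(magnitude=1.0, cell_radius=1.0, direction=load.direction)

    x = initial_nodes / radius if warm else nodes0.copy()
    path = [float(np.average(x[:, 0], weights=node_w)) * radius]
    max_stretch = 1.0
    max_pen = 0.0
    escaped = False
    stalled = 0
    step_cap = opts.step_cap
    mobility = 1.0  # adaptive damping multiplier: loosens during slow creep
    cx_last = best_cx = path[0] / radius
    best_inc = 0

    n_inc = 0
    while n_inc < opts.budget:
        n_inc += 1
        ramp = 1.0 if warm else min(1.0, n_inc / opts.n_ramp)
        p_now = p_star * ramp

        centroid = np.average(x, axis=0, weights=node_w)
        f_ext = p_now * nodal_forces(
            load_hat, x, mesh.surface, centroid=centroid
        )
        areas = _surface_node_areas(x, mesh.surface, surf_ids)
        f_tot = float(np.linalg.norm(f_ext.sum(axis=0)))
        eta = max(f_tot / (node_w.sum() * step_cap), 1e-4) / mobility

        x_prev = x.copy()

        def make_objective(k_pen, eta):
            def objective(xf):
                xn = xf.reshape(-1, 3)
                en, grad = kernel.energy_and_forces(xn)
                # contact penalty on surface nodes (2D xy distance field)
                d, g2 = sdf_grad(xn[surf_ids, :2])
                pen = np.minimum(d, 0.0)
                en += 0.5 * k_pen * float(np.sum(areas * pen**2))
                gc = (k_pen * areas * pen)[:, None] * g2
                grad[surf_ids, 0] += gc[:, 0]
                grad[surf_ids, 1] += gc[:, 1]
                # external load (frozen within the increment)
                en -= float(np.sum(f_ext * xn))
                grad -= f_ext
                # pseudo-time damping
                dx = xn - x_prev
                en += 0.5 * eta * float(np.sum(node_w[:, None] * dx**2))
                grad += eta * node_w[:, None] * dx
                return en, grad.ravel()

            return objective

        accepted = False
        pen_depth = 0.0
        for escalation in range(opts.max_penalty_escalations + 1):
            objective = make_objective(k_pen, eta)
            res = optimize.minimize(
                objective,
                x_prev.ravel(),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": opts.max_iter, "ftol": 1e-12, "gtol": 3e-7},
            )
            x_new = res.x.reshape(-1, 3)
            if np.any(kernel.jacobians(x_new) <= 0):
                # retry the increment with stronger damping
                step_cap *= 0.5
                eta *= 2.0
                if step_cap < 1e-3:
                    logger.warning("element inversion persists; aborting run")
                    return SimOutcome(
                        escaped=False,
                        centroid_path=np.asarray(path),
                        max_principal_stretch=max_stretch,
                        converged=False,
                        max_penetration=max_pen * radius,
                        increments=n_inc,
                        final_nodes=x * radius,
                    )
                continue
            d, _ = sdf_grad(x_new[surf_ids, :2])
            pen_depth = float(-min(np.min(d), 0.0))
            if pen_depth > pen_tol_hat and escalation < opts.max_penalty_escalations:
                k_pen *= 4.0
                continue
            accepted = True
            break
        if not accepted:
            logger.warning("increment not accepted after retries")
        x = x_new
        max_pen = max(max_pen, pen_depth)
        max_stretch = max(max_stretch, kernel.max_principal_stretch(x))
        cx = float(np.average(x[:, 0], weights=node_w))
        path.append(cx * radius)

        if cx > throat_hat + 1.0:
            escaped = True
            break
        move = float(np.max(np.abs(x - x_prev)))
        trapped_suspect = False
        if ramp >= 1.0 and move < opts.disp_tol:
            stalled += 1
            if stalled >= 2:
                trapped_suspect = True
        else:
            stalled = 0
        # no-forward-progress rule: a trapped cell (possibly hovering in a
        # small limit cycle as the travelling load is refreshed) stops
        # gaining ground; an escaping one keeps advancing
        if cx > best_cx + opts.disp_tol:
            best_cx, best_inc = cx, n_inc
        elif ramp >= 1.0 and n_inc - best_inc >= opts.patience:
            trapped_suspect = True
        if trapped_suspect:
            # confirm equilibrium with near-undamped relaxations, refreshing
            # the travelling load between them: a truly trapped cell stays
            # put, a slowly creeping one (or one resting in a mesh-scale
            # corrugation of the energy landscape) breaks loose
            x_conf = x
            cx_conf = cx
            valid = True
            for _cycle in range(3):
                cen = np.average(x_conf, axis=0, weights=node_w)
                f_conf = p_now * nodal_forces(load_hat, x_conf, mesh.surface,
                                              centroid=cen)
                f_ext = f_conf  # seen by make_objective via closure
                conf = optimize.minimize(
                    make_objective(k_pen, eta / 16.0),
                    x_conf.ravel(),
                    jac=True,
                    method="L-BFGS-B",
                    options={"maxiter": 2 * opts.max_iter, "ftol": 1e-12,
                             "gtol": 3e-7},
                )
                x_try = conf.x.reshape(-1, 3)
                if np.any(kernel.jacobians(x_try) <= 0):
                    valid = False
                    break
                x_conf = x_try
                cx_conf = float(np.average(x_conf[:, 0], weights=node_w))
                if cx_conf - cx > 0.05:
                    break
            if valid and cx_conf - cx > 0.05:
                # it moved: no equilibrium here — accept and keep marching
                x = x_conf
                cx = cx_conf
                path.append(cx * radius)
                max_stretch = max(max_stretch, kernel.max_principal_stretch(x))
                d_conf, _ = sdf_grad(x[surf_ids, :2])
                max_pen = max(max_pen, float(-min(np.min(d_conf), 0.0)))
                best_cx, best_inc = cx, n_inc
                stalled = 0
                mobility = min(mobility * 4.0, 8.0)
                if cx > throat_hat + 1.0:
                    escaped = True
                    break
            elif valid:
                stalled = 2
                break
            else:
                # inversion under free slide: inconclusive, march on gently
                stalled = 0
                best_inc = n_inc
                mobility = max(mobility * 0.5, 0.25)
        # adapt the damping: slow-but-steady creep earns a looser leash,
        # backward motion or overshooting tightens it again
        if ramp >= 1.0:
            if cx < cx_last:
                mobility = max(mobility * 0.5, 0.25)
            elif move < 0.3 * step_cap and move >= opts.disp_tol:
                mobility = min(mobility * 2.0, 8.0)
            elif move > step_cap:
                mobility = max(mobility * 0.5, 1.0)
        cx_last = cx

    converged = escaped or stalled >= 2
    if not converged:
        logger.warning(
            "no escape and no equilibrium within %d increments; treating as trapped",
            opts.budget,
        )
    return SimOutcome(
        escaped=escaped,
        centroid_path=np.asarray(path),
        max_principal_stretch=max_stretch,
        converged=converged,
        max_penetration=max_pen * radius,
        increments=n_inc,
        final_nodes=x * radius,
    )


# --- critical-pressure search ----------------------------------------------

_PC_CACHE: dict[tuple, float] = {}


def clear_cache() -> None:
    _PC_CACHE.clear()


def _dimensionless_key(cell: CellSpec, geometry: TrapGeometry, opts: SolverOptions):
    a = cell.diameter
    return (
        round(a / geometry.gap, 9),
        round(geometry.diagonal_major / a, 9),
        round(geometry.diagonal_minor / a, 9),
        round(geometry.fillet_radius / a, 9),
        round(cell.poisson_ratio, 9),
        opts.fingerprint(),
    )


def find_critical_pressure(
    cell: CellSpec,
    geometry: TrapGeometry,
    tolerance: float | None = None,
    seed: int = 0,
    start_pressure: float | None = None,
    options: SolverOptions = SolverOptions(),
    use_cache: bool = False,
) -> CriticalPressureResult:
    """Bisection for the minimum peak pressure P0 (Pa) at which the cell
    escapes through the gap.

    Escape is assumed monotone in P0.  The initial bracket is found by
    doubling from ``start_pressure``; by default that is E/500 Pa — i.e. a
    fixed *dimensionless* start P0/E = 0.002 (1 Pa for a mid-range 500 Pa
    cell).  Scaling the ladder with E keeps the probe sequence congruent
    across moduli, so the solver's exact E-linearity survives the search's
    quantization; the start carries no information about the diameter/gap
    dependence that sweeps are meant to measure.  ``tolerance`` is the
    absolute
    bracket width in Pa at termination; by default 5% of the current upper
    bracket end.  Pc is reported as the upper bracket end — the lowest
    pressure observed to escape.  Cells with a <= g pass freely: Pc = 0.

    All runs are deterministic; ``seed`` is recorded for provenance only.
    """
    if cell.diameter <= geometry.gap:
        return CriticalPressureResult(pc=0.0, bracket=(0.0, 0.0), iterations=0,
                                      tolerance=0.0)
    E = cell.youngs_modulus
    key = _dimensionless_key(cell, geometry, options)
    if use_cache and key in _PC_CACHE:
        p_star = _PC_CACHE[key]
        return CriticalPressureResult(
            pc=p_star * E,
            bracket=(np.nan, p_star * E),
            iterations=0,
            tolerance=(tolerance if tolerance is not None else 0.05 * p_star * E),
        )

    mesh = build_cell_mesh(cell.diameter, resolution=options.mesh_resolution)
    material = MaterialNH.from_engineering(E, cell.poisson_ratio)
    surface = build_pillar_surface(geometry)
    x_offset = _initial_center_x(cell.radius, surface, 0.02 * cell.radius)

    # pressure continuation: every probe starts from the trapped equilibrium
    # found at the highest lower pressure, following the experiment's ramp
    state: np.ndarray | None = None

    def escapes(p0: float) -> bool:
        nonlocal state
        load = ParabolicLoad(magnitude=p0, cell_radius=cell.radius)
        out = simulate_passage(mesh, material, surface, load, options,
                               x_offset, initial_nodes=state)
        if not out.escaped and out.converged:
            state = out.final_nodes
        return out.escaped

    p = E / 500.0 if start_pressure is None else float(start_pressure)
    iterations = 0

    lo, hi = 0.0, None
    for _ in range(16):
        iterations += 1
        if escapes(p):
            hi = p
            break
        lo = p
        p *= 2.0
    if hi is None:
        raise ConvergenceError(
            f"no escape observed up to {p / 2:.3g} Pa; cannot bracket Pc"
        )

    def width_tol(upper):
        return tolerance if tolerance is not None else 0.05 * upper

    while hi - lo > width_tol(hi):
        mid = 0.5 * (lo + hi)
        iterations += 1
        if escapes(mid):
            hi = mid
        else:
            lo = mid
    if not lo < hi:
        raise InconsistentOutcomeError(
            f"degenerate bracket ({lo}, {hi}) — non-monotone outcomes"
        )
    _PC_CACHE[key] = hi / E
    return CriticalPressureResult(
        pc=hi, bracket=(lo, hi), iterations=iterations, tolerance=width_tol(hi)
    )


def pressure_scan(
    cell: CellSpec,
    geometry: TrapGeometry,
    pressures,
    options: SolverOptions = SolverOptions(),
) -> list[bool]:
    """Escape flags over an increasing pressure grid, by continuation.

    Walks the grid from low to high, carrying the trapped equilibrium state
    forward, exactly as the bisection's probes do — a brute-force linear
    search usable as an independent oracle for the bisection threshold.
    """
    mesh = build_cell_mesh(cell.diameter, resolution=options.mesh_resolution)
    material = MaterialNH.from_engineering(cell.youngs_modulus, cell.poisson_ratio)
    surface = build_pillar_surface(geometry)
    x_offset = _initial_center_x(cell.radius, surface, 0.02 * cell.radius)
    pressures = sorted(float(p) for p in pressures)
    state = None
    flags = []
    for p in pressures:
        load = ParabolicLoad(magnitude=p, cell_radius=cell.radius)
        out = simulate_passage(mesh, material, surface, load, options,
                               x_offset, initial_nodes=state)
        flags.append(out.escaped)
        if not out.escaped and out.converged:
            state = out.final_nodes
    return flags


def sweep(
    diameters,
    moduli,
    gaps,
    geometry: TrapGeometry | None = None,
    poisson_ratio: float = 0.3,
    tolerance: float | None = None,
    seed: int = 0,
    options: SolverOptions = SolverOptions(),
) -> list[SweepRecord]:
    """Critical pressure over a (diameter x modulus x gap) grid.

    Combinations with a <= g are recorded directly as Pc = 0.  Because the
    solver is dimensionless, Pc/E is computed once per (diameter, gap) shape
    and reused across moduli.  Failed runs are recorded with
    ``converged=False`` and excluded from downstream regression.
    """
    base = geometry or TrapGeometry(gap=8.0)
    records: list[SweepRecord] = []
    failures = 0
    settings = repr(options.fingerprint())
    for g in gaps:
        geom = replace(base, gap=float(g))
        for a in diameters:
            for E in moduli:
                cell = CellSpec(diameter=float(a), youngs_modulus=float(E),
                                poisson_ratio=poisson_ratio)
                try:
                    res = find_critical_pressure(
                        cell, geom, tolerance=tolerance, seed=seed,
                        options=options, use_cache=True,
                    )
                    records.append(
                        SweepRecord(cell=cell, geometry=geom,
                                    critical_pressure=res.pc, seed=seed,
                                    settings=settings)
                    )
                except (ConvergenceError, MeshError) as exc:
                    failures += 1
                    logger.warning("sweep point (a=%s, E=%s, g=%s) failed: %s",
                                   a, E, g, exc)
                    records.append(
                        SweepRecord(cell=cell, geometry=geom,
                                    critical_pressure=0.0, converged=False,
                                    seed=seed, settings=settings)
                    )
    if failures:
        logger.warning("%d sweep point(s) failed and are flagged", failures)
    return records
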