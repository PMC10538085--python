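"""Contact simulator: escape/trap classification and critical pressure.

These run the full hyperelastic solver at the coarse desk-scale mesh, so a
handful of seconds per simulation is expected.
"""

import numpy as np
import pytest

from pillartrap.contact import (
    MaterialNH,
    SolverOptions,
    build_cell_mesh,
    build_pillar_surface,
    clear_cache,
    find_critical_pressure,
    simulate_passage,
)
from pillartrap.loading import ParabolicLoad
from pillartrap.types import CellSpec, TrapGeometry

COARSE = SolverOptions(mesh_resolution=3)


def _run(diameter, gap, p0, E=430.0, options=COARSE, geometry=None):
    geom = geometry or TrapGeometry(gap=gap)
    mesh = build_cell_mesh(diameter, options.mesh_resolution)
    mat = MaterialNH.from_engineering(E, 0.3)
    surf = build_pillar_surface(geom)
    load = ParabolicLoad(magnitude=p0, cell_radius=diameter / 2)
    return simulate_passage(mesh, mat, surf, load, options)


class TestMaterial:
    def test_parameter_conversion(self):
        m = MaterialNH.from_engineering(430.0, 0.3)
        assert m.c10 == pytest.approx(430.0 / (4 * 1.3))
        assert m.d1 == pytest.approx(6 * 0.4 / 430.0)


class TestPassage:
    def test_small_cell_passes_freely(self):
        out = _run(diameter=7.0, gap=8.0, p0=5.0)
        assert out.escaped
        assert out.converged

    def test_no_load_no_escape(self):
        out = _run(diameter=17.0, gap=8.0, p0=0.0)
        assert not out.escaped
        assert out.converged
        # centroid stays put without a driving force
        assert abs(out.centroid_path[-1] - out.centroid_path[0]) < 0.1

    def test_high_pressure_escapes(self):
        out = _run(diameter=12.0, gap=8.0, p0=300.0)
        assert out.escaped

    def test_pressure_modulus_scaling_leaves_outcome_unchanged(self):
        """(P0, E) -> (2 P0, 2 E) is an exact invariance of the BVP."""
        a = _run(diameter=14.0, gap=8.0, p0=60.0, E=430.0)
        b = _run(diameter=14.0, gap=8.0, p0=120.0, E=860.0)
        assert a.escaped == b.escaped
        assert a.centroid_path[-1] == pytest.approx(b.centroid_path[-1], abs=1e-6)

    def test_penetration_within_tolerance(self):
        out = _run(diameter=17.0, gap=8.0, p0=100.0)
        assert out.max_penetration <= 0.01 * 8.0 + 1e-9


class TestCriticalPressure:
    def test_free_passage_zero(self):
        res = find_critical_pressure(
            CellSpec(diameter=6.0, youngs_modulus=430.0), TrapGeometry(gap=8.0)
        )
        assert res.pc == 0.0
        assert res.iterations == 0

    def test_modulus_linearity(self):
        """Pc(2E) = 2 Pc(E): the dimensionless solver makes the threshold
        exactly linear in E, and the E-proportional probe ladder keeps the
        two searches congruent, so the reported values scale exactly."""
        clear_cache()
        geom = TrapGeometry(gap=8.0)
        r1 = find_critical_pressure(
            CellSpec(diameter=13.0, youngs_modulus=400.0), geom, options=COARSE
        )
        clear_cache()
        r2 = find_critical_pressure(
            CellSpec(diameter=13.0, youngs_modulus=800.0), geom, options=COARSE
        )
        assert r2.pc == pytest.approx(2 * r1.pc, rel=1e-9)

    def test_geometric_scale_invariance(self):
        """Scaling all lengths by lambda leaves Pc unchanged.

        lambda = 2 is exactly representable, so the dimensionless problem
        the solver sees is bit-identical and the invariance is exact; at
        non-dyadic factors the last-ulp rounding of the scaled geometry is
        chaotically amplified by the near-threshold dynamics."""
        lam = 2.0
        clear_cache()
        r1 = find_critical_pressure(
            CellSpec(diameter=12.0, youngs_modulus=430.0),
            TrapGeometry(gap=8.0, diagonal_major=70.0, diagonal_minor=70.0,
                         height=50.0, fillet_radius=2.0),
            options=COARSE,
        )
        clear_cache()
        r2 = find_critical_pressure(
            CellSpec(diameter=12.0 * lam, youngs_modulus=430.0),
            TrapGeometry(gap=8.0 * lam, diagonal_major=70.0 * lam,
                         diagonal_minor=70.0 * lam, height=50.0 * lam,
                         fillet_radius=2.0 * lam),
            options=COARSE,
        )
        assert r2.pc == pytest.approx(r1.pc, rel=1e-9)

    def test_bisection_agrees_with_dense_scan(self):
        """Brute-force oracle: a dense linear pressure scan (same
        continuation process, exhaustive search instead of bisection)
        locates the same escape threshold, within one scan step."""
        from pillartrap.contact import pressure_scan

        cell = CellSpec(diameter=12.0, youngs_modulus=430.0)
        geom = TrapGeometry(gap=8.0)
        clear_cache()
        res = find_critical_pressure(cell, geom, options=COARSE)
        # scan at the bisection's own tolerance granularity (5% of Pc):
        # incremental loading is hysteretic, so a much coarser ladder
        # re-equilibrates less often and detaches earlier
        scan = np.linspace(0.7 * res.pc, 1.3 * res.pc, 13)
        step = scan[1] - scan[0]
        escaped = pressure_scan(cell, geom, scan, options=COARSE)
        first_escape = next(i for i, e in enumerate(escaped) if e)
        assert all(escaped[first_escape:])
        threshold = scan[first_escape]
        assert abs(threshold - res.pc) <= step + 1e-9
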