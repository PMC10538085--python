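"""Flow solver oracles: Poiseuille benchmark, conservation, linearity."""

import numpy as np
import pytest

from pillartrap.flow import (
    FlowConditions,
    cross_gap_velocity,
    gap_mean_pressure,
    pressure_along_gap,
    solve_flow,
    straight_channel_domain,
    trapping_unit_domain,
)
from pillartrap.types import TrapGeometry

_UL = 1e-9 / 60.0


@pytest.fixture(scope="module")
def unit_domain():
    return trapping_unit_domain(TrapGeometry(gap=6.0))


@pytest.fixture(scope="module")
def unit_solutions(unit_domain):
    """Solutions at the three bench flow rates on the 6 um gap unit."""
    return {
        q: solve_flow(unit_domain, FlowConditions(flow_rate=q))
        for q in (1.0, 5.0, 10.0)
    }


class TestChannelOracle:
    def test_poiseuille_pressure_gradient(self):
        """Wide straight channel: centreline pressure gradient matches the
        plane-Poiseuille closed form 12 mu Q / (w h^3) within 5%."""
        length, width = 400.0, 1000.0
        dom = straight_channel_domain(length, width)
        cond = FlowConditions(flow_rate=10.0, channel_width=width)
        sol = solve_flow(dom, cond)
        j = dom.shape[1] // 2
        m = (dom.xc > length / 4) & (dom.xc < 3 * length / 4)
        grad = np.polyfit(dom.xc[m] * 1e-6, sol.p[m, j], 1)[0]
        mu, h, w = cond.viscosity, 50e-6, width * 1e-6
        expected = -12 * mu * (10.0 * _UL) / (w * h**3)
        assert grad == pytest.approx(expected, rel=0.05)

    def test_flux_balance(self):
        dom = straight_channel_domain(300.0, 500.0)
        sol = solve_flow(dom, FlowConditions(flow_rate=5.0, channel_width=500.0))
        qin, qout = sol.inlet_flux(), sol.outlet_flux()
        assert abs(qin - qout) / qin <= 1e-3

    def test_zero_flow_rate_gives_zero_fields(self):
        dom = straight_channel_domain(200.0, 200.0)
        sol = solve_flow(dom, FlowConditions(flow_rate=0.0, channel_width=200.0))
        assert np.abs(sol.u).max() == pytest.approx(0.0, abs=1e-16)
        assert np.abs(sol.p).max() == pytest.approx(0.0, abs=1e-12)


class TestTrappingUnit:
    def test_flux_balance(self, unit_solutions):
        sol = unit_solutions[10.0]
        qin, qout = sol.inlet_flux(), sol.outlet_flux()
        assert abs(qin - qout) / qin <= 1e-3

    def test_divergence_free(self, unit_solutions):
        sol = unit_solutions[10.0]
        assert sol.max_divergence <= 1e-9 * abs(sol.inlet_flux())

    def test_gap_profile_monotone_and_nested(self, unit_solutions):
        """Pressure decreases along the gap; the three flow-rate profiles
        are nested in order of Q."""
        profiles = {}
        for q, sol in unit_solutions.items():
            arc, p = pressure_along_gap(sol)
            assert np.all(np.diff(p) <= 1e-6 * max(abs(p[0]), 1.0))
            profiles[q] = p
        drop = {q: p[0] - p[-1] for q, p in profiles.items()}
        assert drop[1.0] < drop[5.0] < drop[10.0]

    def test_pressure_drop_linear_in_flow_rate(self, unit_solutions):
        """Stokes-regime linearity: dP proportional to Q within 2% across
        the 1/5/10 uL/min bench points."""
        dp = {q: gap_mean_pressure(sol) for q, sol in unit_solutions.items()}
        assert dp[10.0] > 0
        for q in (5.0, 10.0):
            assert dp[q] / q == pytest.approx(dp[1.0] / 1.0, rel=0.02)

    def test_cross_gap_profile_parabolic(self, unit_solutions):
        """Velocity across the 6 um gap is parabolic: best-fit parabola
        achieves R^2 >= 0.99."""
        y, u = cross_gap_velocity(unit_solutions[10.0])
        assert len(y) >= 8
        coef = np.polyfit(y, u, 2)
        resid = u - np.polyval(coef, y)
        r2 = 1 - np.sum(resid**2) / np.sum((u - u.mean()) ** 2)
        assert r2 >= 0.99

    def test_gap_mean_pressure_scales_and_sign(self, unit_solutions):
        dp10 = gap_mean_pressure(unit_solutions[10.0])
        dp5 = gap_mean_pressure(unit_solutions[5.0])
        assert dp10 > 0
        assert dp10 / dp5 == pytest.approx(2.0, rel=0.02)

    def test_uniform_pressure_profile_is_flat(self, unit_solutions):
        """Sanity of the profile extractor itself on a constant field."""
        sol = unit_solutions[10.0]
        flat = type(sol)(
            domain=sol.domain, conditions=sol.conditions, u=sol.u, v=sol.v,
            p=np.full_like(sol.p, 7.0), converged=True,
            picard_iterations=1, max_divergence=0.0,
        )
        _arc, p = pressure_along_gap(flat)
        assert np.allclose(p, 7.0)
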