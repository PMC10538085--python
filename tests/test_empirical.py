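import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pillartrap.empirical import (
    compare_model_orders,
    fit_power_law,
    predict_critical_pressure,
    read_sweep_csv,
    validate_against,
    write_sweep_csv,
)
from pillartrap.errors import (
    InsufficientDataError,
    InvalidInputError,
    UndefinedCorrelationError,
    UnidentifiableModelError,
)
from pillartrap.types import CellSpec, PowerLawModel, SweepRecord, TrapGeometry
from conftest import make_grid_records


class TestPredict:
    @pytest.mark.parametrize(
        "E,a,g,expected",
        [
            (430.0, 17.0, 8.0, 52.43),     # 0.027*430*(17/8)^2
            (100.0, 5.0, 5.0, 2.7),        # a = g -> 0.027*E
            (1.0, 4.0, 2.0, 0.108),        # a = 2g -> 0.027*4
        ],
    )
    def test_worked_examples(self, default_model, E, a, g, expected):
        cell = CellSpec(diameter=a, youngs_modulus=E)
        pc = predict_critical_pressure(default_model, cell, TrapGeometry(gap=g))
        assert pc == pytest.approx(expected, abs=0.005)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            CellSpec(diameter=-1.0, youngs_modulus=430.0)
        with pytest.raises(InvalidInputError):
            TrapGeometry(gap=0.0)
        with pytest.raises(InvalidInputError):
            PowerLawModel(coefficient=-0.1)

    @given(
        E=st.floats(1.0, 1e4),
        a=st.floats(5.0, 40.0),
        g=st.floats(1.0, 12.0),
        lam=st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_linear_in_E_and_scale_invariant(self, E, a, g, lam):
        """P(2E) = 2 P(E); joint rescaling of a and g leaves Pc unchanged."""
        model = PowerLawModel()
        c1 = CellSpec(diameter=a, youngs_modulus=E)
        c2 = CellSpec(diameter=a, youngs_modulus=2 * E)
        geom = TrapGeometry(gap=g)
        p1 = predict_critical_pressure(model, c1, geom)
        assert predict_critical_pressure(model, c2, geom) == pytest.approx(2 * p1)
        scaled = predict_critical_pressure(
            model,
            CellSpec(diameter=lam * a, youngs_modulus=E),
            TrapGeometry(gap=lam * g, diagonal_minor=max(70.0, 20 * lam * g)),
        )
        assert scaled == pytest.approx(p1, rel=1e-12)


class TestFit:
    def test_noiseless_grid_recovers_parameters(self, grid_records):
        fit = fit_power_law(grid_records)
        assert fit.model.coefficient == pytest.approx(0.027, rel=1e-8)
        assert fit.model.exponent == pytest.approx(2.0, rel=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_other_generating_exponents_recovered(self):
        for n_true in (1.3, 2.0, 3.0):
            recs = make_grid_records(coefficient=0.05, exponent=n_true)
            fit = fit_power_law(recs)
            assert fit.model.exponent == pytest.approx(n_true, rel=1e-8)
            assert fit.model.coefficient == pytest.approx(0.05, rel=1e-8)

    def test_nls_objective_agrees_on_noiseless_data(self, grid_records):
        fit = fit_power_law(grid_records, objective="nls")
        assert fit.model.coefficient == pytest.approx(0.027, rel=1e-6)
        assert fit.model.exponent == pytest.approx(2.0, rel=1e-6)

    def test_single_ratio_unidentifiable(self):
        recs = [
            SweepRecord(
                cell=CellSpec(diameter=16.0, youngs_modulus=E),
                geometry=TrapGeometry(gap=8.0),
                critical_pressure=0.027 * E * 4.0,
            )
            for E in (300.0, 400.0, 500.0, 600.0)
        ]
        with pytest.raises(UnidentifiableModelError):
            fit_power_law(recs)
        # but a fixed exponent is fine
        fit = fit_power_law(recs, exponent=2.0)
        assert fit.model.coefficient == pytest.approx(0.027, rel=1e-8)

    def test_insufficient_data(self):
        recs = make_grid_records()[:2]
        with pytest.raises(InsufficientDataError):
            fit_power_law(recs)

    def test_noisy_fit_recovers_within_tolerance(self):
        """Multiplicative lognormal noise sigma=0.1 on 200+ points leaves the
        fitted coefficient within 5% of the generating value."""
        recs = make_grid_records(
            moduli=(350.0, 450.0, 550.0),
            diameters=np.linspace(11, 30, 10),
            gaps=(4.0, 5.5, 7.0, 8.5, 10.0),
            noise_sigma=0.1,
            seed=42,
        )
        assert len(recs) >= 150
        fit = fit_power_law(recs)
        assert fit.model.coefficient == pytest.approx(0.027, rel=0.05)
        assert fit.model.exponent == pytest.approx(2.0, rel=0.05)

    def test_zero_pressure_records_excluded(self):
        recs = make_grid_records() + [
            SweepRecord(
                cell=CellSpec(diameter=5.0, youngs_modulus=400.0),
                geometry=TrapGeometry(gap=8.0),
                critical_pressure=0.0,
            )
        ]
        fit = fit_power_law(recs)
        assert fit.n_points == len(recs) - 1
        assert fit.model.exponent == pytest.approx(2.0, rel=1e-8)


class TestCompareOrders:
    def test_quadratic_generating_model_ranks_first(self, grid_records):
        fits = compare_model_orders(grid_records)
        assert [f.model.exponent for f in fits][0] == 2
        assert fits[0].r_squared == pytest.approx(1.0, abs=1e-10)
        assert all(f.r_squared <= 1.0 + 1e-12 for f in fits)

    def test_each_generating_order_wins(self):
        for n_true in (1, 2, 3):
            recs = make_grid_records(exponent=float(n_true))
            fits = compare_model_orders(recs)
            assert fits[0].model.exponent == n_true

    def test_too_few_records(self):
        with pytest.raises(InsufficientDataError):
            compare_model_orders(make_grid_records()[:2])


class TestValidate:
    def _observations(self, model, cell, gaps):
        return [
            (g, predict_critical_pressure(model, cell, TrapGeometry(gap=g)))
            for g in gaps
        ]

    def test_self_consistency(self, default_model, a549):
        obs = self._observations(default_model, a549, [6.9, 7.8, 8.9, 9.8])
        r2, r = validate_against(default_model, a549, obs)
        assert r2 == pytest.approx(1.0)
        assert r == pytest.approx(1.0)

    def test_offset_observations(self, default_model, a549):
        """A constant offset keeps Pearson r at 1 but lowers R^2 against the
        identity line."""
        obs = [
            (g, pc + 10.0)
            for g, pc in self._observations(default_model, a549, [5.0, 7.0, 9.0, 11.0])
        ]
        r2, r = validate_against(default_model, a549, obs)
        assert r == pytest.approx(1.0)
        assert r2 < 1.0

    def test_constant_observations_rejected(self, default_model, a549):
        with pytest.raises(UndefinedCorrelationError):
            validate_against(default_model, a549, [(5.0, 7.0), (6.0, 7.0), (8.0, 7.0)])

    def test_repeated_gaps_rejected(self, default_model, a549):
        with pytest.raises(InsufficientDataError):
            validate_against(default_model, a549, [(8.0, 1.0), (8.0, 1.0), (8.0, 1.0)])


class TestIO:
    def test_sweep_csv_roundtrip(self, tmp_path, grid_records):
        path = tmp_path / "sweep.csv"
        write_sweep_csv(grid_records, path, header="test dataset")
        back = read_sweep_csv(path)
        assert len(back) == len(grid_records)
        for a, b in zip(grid_records, back):
            assert b.cell.diameter == pytest.approx(a.cell.diameter)
            assert b.critical_pressure == pytest.approx(a.critical_pressure)
        fit = fit_power_law(back)
        assert fit.model.exponent == pytest.approx(2.0, rel=1e-8)
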