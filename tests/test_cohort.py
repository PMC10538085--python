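import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pillartrap.cohort import (
    A549_BINS,
    DEVICE_ARRAYS,
    ArraySequence,
    CaptureRule,
    generate_cohort,
    generate_cohort_binned,
    load_bin_gap_association,
    load_cell_panel,
    operating_pressure_curves,
    recommend_gap,
    route,
)
from pillartrap.errors import (
    DegenerateGeneratorError,
    InvalidBinsError,
    InvalidInputError,
)
from pillartrap.types import PowerLawModel


class TestGenerate:
    def test_large_sample_mean(self):
        """1e5 draws from the A549 model land within 0.05 um of the
        measured mean 17.27 (3 sigma of the standard error)."""
        c = generate_cohort(100_000, seed=7)
        assert c.diameters.mean() == pytest.approx(17.27, abs=0.05)
        assert c.diameters.std() == pytest.approx(2.91, abs=0.05)

    def test_determinism(self):
        a = generate_cohort(1000, seed=3)
        b = generate_cohort(1000, seed=3)
        assert np.array_equal(a.diameters, b.diameters)

    def test_truncation_bounds(self):
        c = generate_cohort(5000, seed=1, truncation=(12.0, 28.0))
        assert c.diameters.min() >= 12.0
        assert c.diameters.max() <= 28.0

    def test_degenerate_truncation_rejected(self):
        with pytest.raises(DegenerateGeneratorError):
            generate_cohort(10, seed=0, truncation=(60.0, 70.0))

    def test_invalid_parameters(self):
        with pytest.raises(InvalidInputError):
            generate_cohort(0)
        with pytest.raises(InvalidInputError):
            generate_cohort(10, sd=-1.0)


class TestBinned:
    def test_single_bin_bounds(self):
        c = generate_cohort_binned(2000, bins=[((12.0, 17.0), 1.0)], seed=2)
        assert c.diameters.min() >= 12.0
        assert c.diameters.max() <= 17.0

    def test_occupancy_matches_proportions(self):
        c = generate_cohort_binned(100_000, seed=5)
        shares = np.array([p for _, p in A549_BINS])
        shares = shares / shares.sum()
        edges = [r for r, _ in A549_BINS]
        for (lo, hi), expected in zip(edges, shares):
            frac = np.mean((c.diameters >= lo) & (c.diameters < hi))
            assert frac == pytest.approx(expected, abs=0.01)

    def test_renormalization_warns(self, caplog):
        with caplog.at_level(logging.WARNING, logger="pillartrap.cohort"):
            generate_cohort_binned(10, seed=0)  # printed shares total 101%
        assert any("renormaliz" in r.message for r in caplog.records)

    def test_overlapping_bins_rejected(self):
        with pytest.raises(InvalidBinsError):
            generate_cohort_binned(
                10, bins=[((12.0, 18.0), 0.5), ((16.0, 20.0), 0.5)]
            )


class TestRoute:
    def test_worked_examples(self):
        """0.25*60 = 15 >= 14 -> first array; 0.25*24 = 6 -> only the 4 um
        array fires."""
        rule = CaptureRule()
        big = generate_cohort(1, seed=0, mean=60.0, sd=0.01)
        r = route(big, DEVICE_ARRAYS, rule)
        assert r.assignment[0] == 0
        mid = generate_cohort(1, seed=0, mean=24.0, sd=0.01)
        r = route(mid, DEVICE_ARRAYS, rule)
        assert DEVICE_ARRAYS.gaps[r.assignment[0]] == 4.0

    def test_conservation(self):
        c = generate_cohort(10_000, seed=11)
        r = route(c, DEVICE_ARRAYS, CaptureRule())
        assert sum(r.captured_counts) + r.escaped_count == len(c)
        assert sum(r.captured_fractions) + r.escaped_fraction == pytest.approx(1.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_monotone_routing(self, seed):
        """With the size-fraction rule, a larger cell is never captured at
        a smaller gap than a smaller cell."""
        c = generate_cohort(200, seed=seed)
        r = route(c, DEVICE_ARRAYS, CaptureRule())
        order = np.argsort(-c.diameters)  # large to small
        ranks = r.assignment[order]
        # captured indices must be non-decreasing once escapes (-1) are
        # mapped past the last array
        ranks = np.where(ranks < 0, len(DEVICE_ARRAYS.gaps), ranks)
        assert np.all(np.diff(ranks) >= 0)

    def test_critical_pressure_rule(self):
        """Operating below a cell's Pc at some array captures it there."""
        c = generate_cohort(500, seed=4)
        rule = CaptureRule(kind="critical-pressure", operating_pressure=30.0,
                           model=PowerLawModel())
        r = route(c, DEVICE_ARRAYS, rule)
        assert sum(r.captured_counts) + r.escaped_count == len(c)
        # every captured cell has predicted Pc above the operating pressure
        for k, gap in enumerate(DEVICE_ARRAYS.gaps):
            d = c.diameters[r.assignment == k]
            if d.size:
                pc = 0.027 * 430.0 * (d / gap) ** 2
                assert np.all(pc > 30.0)

    def test_empty_arrays_rejected(self):
        with pytest.raises(InvalidInputError):
            ArraySequence(gaps=())
        with pytest.raises(InvalidInputError):
            ArraySequence(gaps=(8.0, 10.0))


class TestDesign:
    @pytest.mark.parametrize("d,expected", [(12.0, 3.0), (28.0, 7.0)])
    def test_quarter_rule(self, d, expected):
        assert recommend_gap(d) == pytest.approx(expected)

    def test_zero_fraction_warns(self, caplog):
        with caplog.at_level(logging.WARNING, logger="pillartrap.cohort"):
            assert recommend_gap(15.0, fraction=0.0) == 0.0
        assert any("zero gap" in r.message for r in caplog.records)

    def test_invalid_diameter(self):
        with pytest.raises(InvalidInputError):
            recommend_gap(-3.0)

    def test_curves_decreasing_and_ratio_constant(self):
        panel = load_cell_panel()
        gaps = [4.0, 6.0, 8.0, 10.0]
        df = operating_pressure_curves(panel, gaps)
        assert np.all(df.diff().dropna() < 0)  # strictly decreasing in gap
        # A549 at 8 um
        assert df.loc[8.0, "A549"] == pytest.approx(52.43, abs=0.005)
        # between-type ratio is gap-independent under the power law
        ratio = df["A549"] / df["MDA-MB-231"]
        expected = (430 * 17**2) / (206 * 15.5**2)
        assert np.allclose(ratio, expected, rtol=1e-12)

    def test_panel_contents(self):
        panel = {e.name: e for e in load_cell_panel()}
        assert panel["A549"].stiffness == 430
        assert panel["SW480"].diameter == 11
        assert len(panel) == 6

    def test_bin_gap_association_fixture(self):
        df = load_bin_gap_association()
        assert len(df) == 4
        assert df["population_share"].sum() == pytest.approx(1.01)
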