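"""Incidence averaging, susceptible population and case projection."""

import numpy as np
import pandas as pd
import pytest

from bcfollow.containers import AGES, AgeSchedule, InputError, PopulationFrame
from bcfollow.epidemiology import (
    mean_incidence,
    project_cases,
    susceptible_population,
)

from conftest import schedule_from, tidy_frame


class TestMeanIncidence:
    def test_average_of_yearly_ratios(self):
        """Two years with 10/1000 and 20/1000 average to 1.5%."""
        cn = tidy_frame({(2007, 50): 10, (2008, 50): 20})
        pr = tidy_frame({(2007, 50): 1000, (2008, 50): 1000})
        sched = mean_incidence(cn, pr, [2007, 2008])
        assert sched.fraction[50] == pytest.approx(0.015)
        assert sched.rate[50] == pytest.approx(1500.0)  # per 100,000
        assert np.all(sched.rate[AGES != 50] == 0)

    def test_no_cases_means_zero_everywhere(self):
        cn = tidy_frame({(2007, 40): 0, (2007, 60): 0})
        pr = tidy_frame({(2007, 40): 500, (2007, 60): 800})
        assert np.all(mean_incidence(cn, pr, [2007]).rate == 0)

    def test_linearity_in_case_counts(self):
        """Doubling every cell doubles every rate (brute-force recheck)."""
        rng = np.random.default_rng(11)
        years, ages = [2007, 2008, 2009], [40, 50, 60, 70]
        cn_cells = {(y, a): int(rng.integers(0, 30)) for y in years for a in ages}
        pr_cells = {(y, a): float(rng.integers(500, 5000)) for y in years for a in ages}
        cn, pr = tidy_frame(cn_cells), tidy_frame(pr_cells)
        doubled = tidy_frame({k: 2 * v for k, v in cn_cells.items()})
        once = mean_incidence(cn, pr, years).fraction
        twice = mean_incidence(doubled, pr, years).fraction
        np.testing.assert_allclose(twice, 2 * once, rtol=1e-12)
        for a in ages:  # literal recomputation of the averaged ratios
            expected = np.mean([cn_cells[y, a] / pr_cells[y, a] for y in years])
            assert once[a] == pytest.approx(expected, rel=1e-12)

    def test_zero_at_risk_with_cases_is_undefined(self):
        cn = tidy_frame({(2007, 50): 5})
        pr = tidy_frame({(2007, 50): 0})
        with pytest.raises(InputError, match="undefined rate"):
            mean_incidence(cn, pr, [2007])

    def test_zero_at_risk_without_cases_counts_as_zero_ratio(self):
        cn = tidy_frame({(2007, 50): 0, (2008, 50): 10})
        pr = tidy_frame({(2007, 50): 0, (2008, 50): 1000})
        assert mean_incidence(cn, pr, [2007, 2008]).fraction[50] == pytest.approx(0.005)

    def test_missing_year_and_missing_cell_rejected(self):
        cn = tidy_frame({(2007, 50): 1, (2007, 51): 2, (2008, 50): 1})
        pr = tidy_frame({(2007, 50): 10, (2007, 51): 10, (2008, 50): 10, (2008, 51): 10})
        with pytest.raises(InputError):
            mean_incidence(cn, pr, [2007, 2009])  # year absent
        with pytest.raises(InputError, match="missing"):
            mean_incidence(cn, pr, [2007, 2008])  # (2008, 51) absent


class TestSusceptiblePopulation:
    def test_projection_times_share(self):
        projected = tidy_frame({(2014, 50): 1000.0})
        shares = schedule_from({50: 0.4}, basis="share", per=1.0)
        ps = susceptible_population(projected, shares, horizon=(2014, 2014))
        assert ps.matrix([2014]).loc[2014, 50] == pytest.approx(400.0)

    @pytest.mark.parametrize("share,factor", [(0.0, 0.0), (1.0, 1.0)])
    def test_degenerate_shares(self, share, factor):
        projected = tidy_frame({(2014, a): 100.0 * a for a in (30, 50, 70)})
        shares = AgeSchedule(np.full(101, share), basis="share", per=1.0)
        ps = susceptible_population(projected, shares, horizon=(2014, 2014))
        np.testing.assert_allclose(
            ps.matrix([2014]).to_numpy(),
            factor * projected.matrix([2014]).to_numpy(),
        )

    def test_share_above_one_rejected(self):
        projected = tidy_frame({(2014, 50): 100.0})
        shares = AgeSchedule(np.full(101, 1.5), basis="share", per=1.0)
        with pytest.raises(InputError):
            susceptible_population(projected, shares, horizon=(2014, 2014))


class TestProjectCases:
    def test_zero_inputs_zero_cases(self):
        Io = schedule_from({})
        ps = tidy_frame({(2013, 50): 1000.0, (2014, 50): 1000.0})
        cm = project_cases(Io, ps, None, horizon=(2013, 2014))
        assert cm.cases.to_numpy().sum() == 0

    def test_incidence_times_population(self):
        Io = schedule_from({50: 0.001})
        ps = tidy_frame({(2013, 50): 100_000.0})
        cm = project_cases(Io, ps, None, horizon=(2013, 2013))
        assert cm.cases.loc[2013, 50] == pytest.approx(100.0)

    def test_zero_incidence_conserves_carried_cohorts(self):
        """With Io = 0 the projection is exactly the aged prior stock."""
        Io = schedule_from({})
        ps = tidy_frame(
            {(y, a): 1000.0 for y in (2013, 2014, 2015) for a in range(40, 80)}
        )
        priors = tidy_frame({(2010, 60): 30.0, (2012, 99): 7.0}, name="priors")
        cm = project_cases(Io, ps, priors, horizon=(2013, 2015))
        assert cm.cases.loc[2013, 60] == 30.0
        assert cm.cases.loc[2014, 61] == 30.0
        assert cm.cases.loc[2015, 62] == 30.0
        # open age bin absorbs women aging past 100
        assert cm.cases.loc[2014, 100] == 7.0
        assert cm.cases.loc[2015, 100] == 7.0
        assert cm.cases.to_numpy().sum() == pytest.approx(3 * 37.0)

    def test_homogeneity_in_population(self):
        Io = schedule_from({50: 0.002, 60: 0.001})
        cells = {(2013, 50): 1000.0, (2013, 60): 2000.0,
                 (2014, 50): 1100.0, (2014, 60): 2100.0}
        ps = tidy_frame(cells)
        scaled = tidy_frame({k: 3.5 * v for k, v in cells.items()})
        base = project_cases(Io, ps, None, horizon=(2013, 2014))
        big = project_cases(Io, scaled, None, horizon=(2013, 2014))
        np.testing.assert_allclose(
            big.incident().to_numpy(), 3.5 * base.incident().to_numpy(), rtol=1e-12
        )

    def test_small_case_oracle_both_bracket_readings(self):
        """Literal loop recomputation over 3 years × 3 ages, both forms."""
        ages, years = [50, 51, 52], [2013, 2014, 2015]
        io = {50: 0.01, 51: 0.02, 52: 0.005}
        ps_cells = {(y, a): 100.0 * (a - 49) + (y - 2013) for y in years for a in ages}
        prior_cells = {(2011, 50): 4.0, (2012, 51): 6.0}
        Io = schedule_from(io)
        ps = tidy_frame(ps_cells)
        priors = tidy_frame(prior_cells, name="priors")

        carried = {}  # prior stock aged forward, keyed by (year, age)
        at_ref = {50: 4.0, 51: 6.0}
        for y in years:
            for a, v in at_ref.items():
                carried[y, min(a + y - 2013, 100)] = (
                    carried.get((y, min(a + y - 2013, 100)), 0.0) + v
                )

        cm = project_cases(Io, ps, priors, horizon=(2013, 2015))
        for y in years:
            for a in range(101):
                expected = io.get(a, 0.0) * ps_cells.get((y, a), 0.0) + carried.get(
                    (y, a), 0.0
                )
                assert cm.cases.loc[y, a] == pytest.approx(expected, abs=1e-12)

        literal = project_cases(Io, ps, priors, horizon=(2013, 2015),
                                literal_bracket=True)
        for y in years:
            for a in range(101):
                expected = io.get(a, 0.0) * (
                    ps_cells.get((y, a), 0.0) + carried.get((y, a), 0.0)
                )
                assert literal.cases.loc[y, a] == pytest.approx(expected, abs=1e-12)

    def test_horizon_before_reference_year_rejected(self):
        Io = schedule_from({50: 0.001})
        ps = tidy_frame({(2012, 50): 100.0, (2013, 50): 100.0})
        with pytest.raises(InputError):
            project_cases(Io, ps, None, horizon=(2012, 2013))


def test_projected_totals_grow_through_horizon(pipeline_small):
    """Served cases rise year over year as the population ages and grows."""
    totals = pipeline_small.cases.total_by_year()
    assert (np.diff(totals.to_numpy()) > 0).all()
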