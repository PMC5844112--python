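"""Lognormal cost process, quantile estimator and scenario machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bcfollow.containers import AGES, CaseMatrix, InputError
from bcfollow.costing import CostParameters
from bcfollow.risk_var import (
    ScenarioInputs,
    ScenarioSpec,
    ShockSpec,
    StochasticCostProcess,
    base_scenario,
    default_scenarios,
    estimate_lognormal_params,
    max_expected_cost_var,
    optimistic_scenario,
    pessimistic_scenario,
    run_scenario,
    simulate_cost_path,
)
from bcfollow.survival_cycles import SurvivalConfig

from conftest import flat_schedule, single_cohort, tidy_frame

Z95 = stats.norm.ppf(0.95)


@pytest.fixture()
def simple_inputs():
    """A small but fully populated ScenarioInputs."""
    years = range(2013, 2031)
    new = pd.Series(np.linspace(1000.0, 3000.0, 18), index=years)
    prior = pd.Series(np.linspace(500.0, 100.0, 18), index=years)
    return ScenarioInputs(
        new_totals=new,
        prior_totals=prior,
        cost_params=CostParameters(),
    )


class TestSimulateCostPath:
    def test_zero_volatility_is_pure_drift(self):
        proc = StochasticCostProcess(c0=100.0, mu=0.04, sigma=0.0)
        path = simulate_cost_path(proc, 10, np.zeros(10))
        np.testing.assert_allclose(
            path, 100.0 * np.exp(0.04 * np.arange(1, 11)), rtol=1e-12
        )

    def test_mean_matches_lognormal_closed_form(self):
        proc = StochasticCostProcess(c0=50.0, mu=0.03, sigma=0.2)
        rng = np.random.default_rng(21)
        paths = np.array([simulate_cost_path(proc, 5, rng) for _ in range(20_000)])
        for d in range(5):
            expected = 50.0 * np.exp(0.03 * (d + 1))
            se = expected * np.sqrt(
                (np.exp(0.2**2 * (d + 1)) - 1) / 20_000
            )
            assert abs(paths[:, d].mean() - expected) < 3 * se

    def test_quantile_matches_analytic_lognormal(self):
        proc = StochasticCostProcess(c0=50.0, mu=0.03, sigma=0.2)
        rng = np.random.default_rng(22)
        paths = np.array([simulate_cost_path(proc, 4, rng) for _ in range(20_000)])
        d = 4
        analytic = 50.0 * np.exp(
            (0.03 - 0.02) * d + 0.2 * np.sqrt(d) * Z95
        )
        empirical = np.quantile(paths[:, d - 1], 0.95)
        assert empirical == pytest.approx(analytic, rel=0.02)

    def test_invalid_process_rejected(self):
        with pytest.raises(InputError):
            StochasticCostProcess(c0=0.0)
        with pytest.raises(InputError):
            StochasticCostProcess(c0=1.0, sigma=-0.1)
        with pytest.raises(InputError):
            simulate_cost_path(StochasticCostProcess(c0=1.0), 0, np.zeros(1))


class TestEstimateLognormalParams:
    def test_constant_series(self):
        mu, sigma = estimate_lognormal_params([100.0] * 10)
        assert mu == pytest.approx(0.0, abs=1e-12)
        assert sigma == pytest.approx(0.0, abs=1e-12)

    def test_exact_three_percent_growth(self):
        series = 100.0 * 1.03 ** np.arange(10)
        mu, sigma = estimate_lognormal_params(series)
        assert sigma == pytest.approx(0.0, abs=1e-10)
        assert mu == pytest.approx(np.log(1.03), abs=1e-10)

    def test_round_trip_through_simulation(self):
        proc = StochasticCostProcess(c0=10.0, mu=0.07, sigma=0.0)
        path = simulate_cost_path(proc, 12, np.zeros(12))
        mu, sigma = estimate_lognormal_params(path)
        assert mu == pytest.approx(0.07, abs=1e-10)
        assert sigma == pytest.approx(0.0, abs=1e-10)

    def test_recovery_from_stochastic_paths(self):
        """Mean of 200 per-path estimates recovers (μ, σ) within 3 SE."""
        true_mu, true_sigma = 0.05, 0.2
        proc = StochasticCostProcess(c0=100.0, mu=true_mu, sigma=true_sigma)
        rng = np.random.default_rng(31)
        est = np.array(
            [estimate_lognormal_params(simulate_cost_path(proc, 30, rng))
             for _ in range(200)]
        )
        for col, truth in ((0, true_mu), (1, true_sigma)):
            mean = est[:, col].mean()
            se = est[:, col].std(ddof=1) / np.sqrt(200)
            assert abs(mean - truth) < 3 * se

    def test_invalid_series_rejected(self):
        with pytest.raises(InputError):
            estimate_lognormal_params([1.0, 2.0])
        with pytest.raises(InputError):
            estimate_lognormal_params([1.0, -2.0, 3.0])


class TestMaxExpectedCostVar:
    def test_constant_sample(self):
        assert max_expected_cost_var([7.0] * 50) == 7.0

    def test_nearest_rank_on_integers(self):
        sample = np.arange(1, 101)
        assert max_expected_cost_var(sample, alpha=0.05) == 95.0

    def test_tail_exceedance_bound(self):
        rng = np.random.default_rng(41)
        sample = rng.lognormal(0.0, 0.3, 777)
        for alpha in (0.01, 0.05, 0.10):
            vc = max_expected_cost_var(sample, alpha)
            assert (sample > vc).sum() <= np.ceil(alpha * sample.size)

    def test_monotone_in_alpha_and_scale_equivariant(self):
        rng = np.random.default_rng(42)
        sample = rng.lognormal(1.0, 0.5, 2000)
        cutoffs = [max_expected_cost_var(sample, a) for a in (0.01, 0.05, 0.1, 0.5)]
        assert all(a >= b for a, b in zip(cutoffs, cutoffs[1:]))
        assert max_expected_cost_var(3.0 * sample, 0.05) == pytest.approx(
            3.0 * max_expected_cost_var(sample, 0.05), rel=1e-12
        )

    def test_lognormal_sample_matches_analytic_quantile(self):
        rng = np.random.default_rng(43)
        mu, sigma = 2.0, 0.3
        sample = rng.lognormal(mu, sigma, 5000)
        analytic = np.exp(mu + sigma * Z95)
        assert max_expected_cost_var(sample, 0.05) == pytest.approx(analytic, rel=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            max_expected_cost_var([])


class TestShockSpec:
    def test_point_mass(self):
        assert ShockSpec.point(1.0).ppf(0.123) == 1.0
        assert ShockSpec.point(1.0).is_unit

    @pytest.mark.parametrize(
        "shock",
        [
            ShockSpec.truncated_lognormal(1.0, 1.10, median=1.05),
            ShockSpec.truncated_lognormal(0.90, 1.00, median=0.95),
            ShockSpec.uniform(0.90, 1.00),
        ],
    )
    def test_support_and_monotonicity(self, shock):
        us = np.linspace(0.001, 0.999, 41)
        vals = np.array([shock.ppf(u) for u in us])
        assert np.all(np.diff(vals) >= 0)
        assert vals.min() >= shock.low - 1e-9
        assert vals.max() <= shock.high + 1e-9

    def test_truncated_lognormal_median(self):
        shock = ShockSpec.truncated_lognormal(1.0, 1.10, median=1.05)
        assert shock.ppf(0.5) == pytest.approx(1.05, abs=0.01)


class TestRunScenario:
    def test_degenerate_scenario_equals_deterministic_sum(self, simple_inputs):
        spec = base_scenario(seed=9, n_iterations=500, process_sigma=0.0)
        result = run_scenario(spec, simple_inputs)
        years = np.array(simple_inputs.new_totals.index)
        window = (years >= 2013) & (years <= 2026)
        caseload = (
            simple_inputs.prior_totals + 1.0 * simple_inputs.new_totals
        ).to_numpy()
        expected = (caseload * simple_inputs.unit_costs() * 1.0 * 1.0)[window].sum()
        assert result.var_cutoff == expected
        assert np.all(result.iteration_costs == expected)
        assert result.amortized_annual == expected / 18

    def test_fixed_seed_reproducible(self, simple_inputs):
        spec = pessimistic_scenario(seed=17, n_iterations=400)
        a = run_scenario(spec, simple_inputs)
        b = run_scenario(spec, simple_inputs)
        np.testing.assert_array_equal(a.iteration_costs, b.iteration_costs)
        assert a.var_cutoff == b.var_cutoff

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_matched_seed_scenario_ordering(self, simple_inputs):
        for seed in range(10):
            specs = default_scenarios(seed=seed, n_iterations=150)
            cutoffs = {
                name: run_scenario(spec, simple_inputs).var_cutoff
                for name, spec in specs.items()
            }
            assert cutoffs["optimistic"] <= cutoffs["base"] <= cutoffs["pessimistic"]

    def test_small_iteration_count_warns(self, simple_inputs):
        spec = base_scenario(seed=1, n_iterations=50)
        with pytest.warns(UserWarning, match="quantile error"):
            run_scenario(spec, simple_inputs)

    def test_fatality_shock_requires_components(self, simple_inputs):
        spec = ScenarioSpec(
            name="fatal",
            fatality_shock=ShockSpec.uniform(1.05, 1.15),
            n_iterations=30,
            seed=2,
        )
        with pytest.warns(UserWarning):
            with pytest.raises(InputError, match="fatality shocks"):
                run_scenario(spec, simple_inputs)

    def test_fatality_shock_lowers_surviving_caseload(self):
        """Higher fatality ⇒ fewer survivors ⇒ cheaper extension."""
        cases = single_cohort(2013, 50, 1000.0)
        inputs = ScenarioInputs.from_components(
            cases,
            None,
            flat_schedule(0.05),
            CostParameters(),
            SurvivalConfig(last_year=2016),
        )
        up = ScenarioSpec(
            name="fatal-up",
            fatality_shock=ShockSpec.uniform(1.2, 1.2),
            n_iterations=25,
            seed=3,
            process_sigma=0.0,
        )
        flat = base_scenario(seed=3, n_iterations=25, process_sigma=0.0)
        with pytest.warns(UserWarning):
            shocked = run_scenario(up, inputs)
        with pytest.warns(UserWarning):
            plain = run_scenario(flat, inputs)
        assert shocked.var_cutoff < plain.var_cutoff

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_per_year_profile_covers_horizon(self, simple_inputs):
        spec = base_scenario(seed=5, n_iterations=200)
        result = run_scenario(spec, simple_inputs)
        assert list(result.per_year_var.index) == list(range(2013, 2031))
        assert (result.per_year_var > 0).all()
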