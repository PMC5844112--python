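"""Monte-Carlo maximum expected cost (inverted Value-at-Risk).

The annual extension cost is evolved through a lognormal stochastic
process,

.. math:: C_i = C_0 \\exp\\left[(\\mu - \\sigma^2/2)\\Delta_i
                + \\sigma W_{\\Delta_i}\\right], \\qquad
          W_{\\Delta} = \\textstyle\\sum_{t \\le \\Delta} \\eta_t,\\;
          \\eta_t \\sim N(0, 1),

whose marginal at elapsed time :math:`\\Delta_i` is the standard
lognormal :math:`C_0 e^{(\\mu-\\sigma^2/2)\\Delta_i +
\\sigma\\sqrt{\\Delta_i}\\,\\xi}` with :math:`\\xi \\sim N(0,1)`.
Scenario shocks (multipliers on incidence, fatality and unit cost,
truncated-lognormal by default) perturb the deterministic pipeline per
iteration; the *maximum expected cost* is the right-tail cut-off

.. math:: V_c : \\; P[c(W) > V_c] \\le \\alpha,

estimated as the nearest-rank :math:`(1-\\alpha)` empirical quantile of
the simulated cumulative costs — the amount exceeded by only
:math:`\\alpha` of the Monte-Carlo iterations.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AgeSchedule, CaseMatrix, ConfigurationError, InputError, PopulationFrame
from .costing import CostParameters, CostSchedule, monitoring_unit_cost
from .survival_cycles import SurvivalConfig, run_cycles

__all__ = [
    "ShockSpec",
    "ScenarioSpec",
    "StochasticCostProcess",
    "ScenarioInputs",
    "VaRResult",
    "simulate_cost_path",
    "estimate_lognormal_params",
    "max_expected_cost_var",
    "run_scenario",
    "base_scenario",
    "pessimistic_scenario",
    "optimistic_scenario",
    "default_scenarios",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShockSpec:
    """A positive multiplier distribution applied once per iteration.

    ``kind`` is ``"point"`` (degenerate), ``"trunc-lognormal"``
    (lognormal restricted to [low, high], the default family for the
    pessimistic/optimistic ±10% bands) or ``"uniform"``.  Sampling goes
    through :meth:`ppf` so that matched uniform draws couple scenarios
    (common random numbers).
    """

    kind: str = "point"
    value: float = 1.0
    low: float = 1.0
    high: float = 1.0
    median: float = 1.0
    sigma: float = 0.03

    def __post_init__(self) -> None:
        if self.kind not in ("point", "trunc-lognormal", "uniform"):
            raise ConfigurationError(f"unknown shock kind {self.kind!r}")
        if min(self.value, self.low, self.high, self.median) <= 0:
            raise ConfigurationError("shock multipliers must be positive")
        if self.kind != "point" and self.low > self.high:
            raise ConfigurationError("shock bounds must satisfy low <= high")
        if self.sigma <= 0:
            raise ConfigurationError("shock sigma must be positive")

    @classmethod
    def point(cls, value: float = 1.0) -> "ShockSpec":
        return cls(kind="point", value=value)

    @classmethod
    def truncated_lognormal(
        cls, low: float, high: float, median: float | None = None, sigma: float = 0.03
    ) -> "ShockSpec":
        if median is None:
            median = math.sqrt(low * high)
        return cls(kind="trunc-lognormal", low=low, high=high, median=median, sigma=sigma)

    @classmethod
    def uniform(cls, low: float, high: float) -> "ShockSpec":
        return cls(kind="uniform", low=low, high=high)

    @property
    def is_unit(self) -> bool:
        return self.kind == "point" and self.value == 1.0

    def ppf(self, u: float) -> float:
        """Quantile function; monotone in ``u`` for every kind."""
        if self.kind == "point":
            return self.value
        if self.kind == "uniform":
            return self.low + (self.high - self.low) * u
        loc = math.log(self.median)
        a = (math.log(self.low) - loc) / self.sigma
        b = (math.log(self.high) - loc) / self.sigma
        return float(np.exp(stats.truncnorm.ppf(u, a, b, loc=loc, scale=self.sigma)))


@dataclass(frozen=True)
class ScenarioSpec:
    """One Monte-Carlo scenario: shocks, process volatility, iteration count."""

    name: str
    incidence_shock: ShockSpec = field(default_factory=ShockSpec.point)
    cost_shock: ShockSpec = field(default_factory=ShockSpec.point)
    fatality_shock: ShockSpec = field(default_factory=ShockSpec.point)
    n_iterations: int = 5000
    alpha: float = 0.05
    seed: int = 0
    process_mu: float = 0.0
    process_sigma: float = 0.10

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.process_sigma < 0:
            raise ConfigurationError("process_sigma must be nonnegative")


@dataclass(frozen=True)
class StochasticCostProcess:
    """Lognormal cost process: initial cost, drift and volatility."""

    c0: float
    mu: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise InputError("initial cost C0 must be positive")
        if self.sigma < 0:
            raise InputError("volatility sigma must be nonnegative")


def simulate_cost_path(
    proc: StochasticCostProcess,
    horizon: int,
    draws: np.ndarray | np.random.Generator,
) -> np.ndarray:
    """Simulate one cost path C_1..C_horizon (elapsed years Δ = 1..horizon).

    ``draws`` supplies the i.i.d. standard-normal annual increments
    (either directly or as a generator to draw from); their running sum
    is the Brownian path, so the marginal of ``C_Δ`` is lognormal with
    log-mean :math:`\\log C_0 + (\\mu - \\sigma^2/2)\\Delta` and
    log-sd :math:`\\sigma\\sqrt{\\Delta}`.
    """
    if horizon < 1:
        raise InputError("horizon must be >= 1")
    if isinstance(draws, np.random.Generator):
        eta = draws.standard_normal(horizon)
    else:
        eta = np.asarray(draws, dtype=float)
        if eta.shape[0] < horizon:
            raise InputError("not enough normal draws for the horizon")
        eta = eta[:horizon]
    delta = np.arange(1, horizon + 1, dtype=float)
    w = np.cumsum(eta)
    return proc.c0 * np.exp((proc.mu - proc.sigma**2 / 2.0) * delta + proc.sigma * w)


def estimate_lognormal_params(annual_costs) -> tuple[float, float]:
    """Estimate (μ, σ) of the lognormal process from an annual cost series.

    σ is the sample standard deviation of log year-over-year ratios and
    μ their mean plus σ²/2 (so a deterministic 3%-growth series maps to
    μ = ln 1.03, σ = 0).  Accepts a :class:`~bcfollow.costing.CostSchedule`
    or any positive sequence of at least three annual costs.
    """
    if isinstance(annual_costs, CostSchedule):
        costs = annual_costs.annual_totals.to_numpy(dtype=float)
    else:
        costs = np.asarray(annual_costs, dtype=float)
    if costs.ndim != 1 or costs.size < 3:
        raise InputError("need at least 3 years of annual costs")
    if np.any(costs <= 0) or not np.all(np.isfinite(costs)):
        raise InputError("annual costs must be positive and finite")
    r = np.diff(np.log(costs))
    sigma = float(np.std(r, ddof=1))
    mu = float(np.mean(r) + sigma**2 / 2.0)
    return mu, sigma


def max_expected_cost_var(iteration_costs, alpha: float = 0.05) -> float:
    """Nearest-rank (1−α) right-tail quantile of simulated costs.

    Returns the ⌈(1−α)·n⌉-th order statistic, so at most ⌈α·n⌉ sample
    points strictly exceed the cut-off.
    """
    sample = np.asarray(iteration_costs, dtype=float)
    if sample.size == 0:
        raise InputError("empty cost sample")
    if not 0 < alpha < 1:
        raise InputError("alpha must lie in (0, 1)")
    rank = math.ceil((1.0 - alpha) * sample.size)
    return float(np.sort(sample)[rank - 1])


@dataclass
class ScenarioInputs:
    """Deterministic pipeline state shared by every Monte-Carlo iteration.

    The caseload decomposes as prior (fixed) + new (scales linearly with
    the incidence multiplier); the full component objects are retained
    so that fatality shocks, which break that linearity, can rerun the
    cycle recursion per iteration.
    """

    new_totals: pd.Series
    prior_totals: pd.Series
    cost_params: CostParameters
    cumulative_window: tuple[int, int] = (2013, 2026)
    amortization_years: int = 18
    new_cases: CaseMatrix | None = None
    prior_cohorts: PopulationFrame | None = None
    fatality: AgeSchedule | None = None
    survival_cfg: SurvivalConfig | None = None
    ref_year: int = 2013

    def __post_init__(self) -> None:
        if not self.new_totals.index.equals(self.prior_totals.index):
            raise InputError("new and prior caseload series must share years")
        if self.amortization_years < 1:
            raise InputError("amortization_years must be >= 1")

    @classmethod
    def from_components(
        cls,
        cases: CaseMatrix,
        prior_cohorts: PopulationFrame | None,
        fatality: AgeSchedule,
        cost_params: CostParameters,
        survival_cfg: SurvivalConfig = SurvivalConfig(),
        cumulative_window: tuple[int, int] = (2013, 2026),
        amortization_years: int = 18,
        ref_year: int = 2013,
    ) -> "ScenarioInputs":
        """Build by splitting the cycle recursion into new/prior parts."""
        new_tbl = run_cycles(cases, None, fatality, survival_cfg, ref_year=ref_year)
        new_totals = new_tbl.totals()
        if prior_cohorts is not None and not prior_cohorts.data.empty:
            zero = CaseMatrix(cases=cases.incident() * 0.0)
            prior_tbl = run_cycles(zero, prior_cohorts, fatality, survival_cfg, ref_year=ref_year)
            prior_totals = prior_tbl.totals()
        else:
            prior_totals = new_totals * 0.0
        return cls(
            new_totals=new_totals,
            prior_totals=prior_totals,
            cost_params=cost_params,
            cumulative_window=cumulative_window,
            amortization_years=amortization_years,
            new_cases=cases,
            prior_cohorts=prior_cohorts,
            fatality=fatality,
            survival_cfg=survival_cfg,
            ref_year=ref_year,
        )

    def unit_costs(self) -> np.ndarray:
        years = [int(y) for y in self.new_totals.index]
        return np.array([monitoring_unit_cost(self.cost_params, y) for y in years])


@dataclass
class VaRResult:
    """Outcome of one scenario run.

    ``var_cutoff`` and ``amortized_annual`` are in pesos; reporting
    converts to millions.  ``per_year_var`` applies the same
    nearest-rank rule to each year's simulated cost.
    """

    scenario: str
    iteration_costs: np.ndarray = field(repr=False)
    var_cutoff: float
    level: float
    amortized_annual: float
    amortization_years: int
    horizon: tuple[int, int]
    seed: int
    n_iterations: int
    per_year_var: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.level >= 0.5 and self.var_cutoff < np.median(self.iteration_costs):
            raise InputError("V_c below the sample median at level >= 0.5")

    def summary(self) -> dict:
        return {
            "scenario": self.scenario,
            "var_cutoff_pesos": self.var_cutoff,
            "var_cutoff_million": self.var_cutoff / 1e6,
            "amortized_annual_pesos": self.amortized_annual,
            "amortized_annual_million": self.amortized_annual / 1e6,
            "quantile_level": self.level,
            "amortization_years": self.amortization_years,
            "horizon": list(self.horizon),
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2, sort_keys=True))

    def iterations_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"iteration": np.arange(self.iteration_costs.size),
             "cumulative_cost": self.iteration_costs}
        ).to_csv(path, index=False)


def _iteration_caseload(
    spec: ScenarioSpec, inputs: ScenarioInputs, m_inc: float, m_fat: float
) -> np.ndarray:
    if m_fat == 1.0 or spec.fatality_shock.is_unit:
        return (inputs.prior_totals + m_inc * inputs.new_totals).to_numpy()
    if inputs.new_cases is None or inputs.fatality is None:
        raise InputError(
            "fatality shocks require full pipeline components in ScenarioInputs"
        )
    shocked = AgeSchedule.from_fraction(
        np.clip(inputs.fatality.fraction * m_fat, 0.0, 1.0),
        basis=inputs.fatality.basis,
    )
    scaled = CaseMatrix(cases=inputs.new_cases.incident() * m_inc)
    tbl = run_cycles(
        scaled, inputs.prior_cohorts, shocked,
        inputs.survival_cfg or SurvivalConfig(), ref_year=inputs.ref_year,
    )
    return tbl.totals().to_numpy()


def run_scenario(spec: ScenarioSpec, inputs: ScenarioInputs) -> VaRResult:
    """Run one Monte-Carlo scenario and estimate the maximum expected cost.

    Each iteration draws shock multipliers and a stochastic cost path
    from its own deterministic substream (seeded from ``spec.seed``),
    rebuilds the annual extension cost, and records the cumulative cost
    over the configured window.  Matched seeds across scenarios couple
    the draws, giving the optimistic ≤ base ≤ pessimistic ordering.
    """
    if spec.alpha * spec.n_iterations < 20:
        warnings.warn(
            f"only ~{spec.alpha * spec.n_iterations:.1f} iterations fall in the "
            f"{spec.alpha:.0%} tail; the quantile error of V_c is large",
            stacklevel=2,
        )
    years = np.array([int(y) for y in inputs.new_totals.index])
    ks = inputs.unit_costs()
    delta = years - years[0]
    lo, hi = inputs.cumulative_window
    window = (years >= lo) & (years <= hi)
    drift = (spec.process_mu - spec.process_sigma**2 / 2.0) * delta

    children = np.random.SeedSequence(spec.seed).spawn(spec.n_iterations)
    cum = np.empty(spec.n_iterations)
    annual_paths = np.empty((spec.n_iterations, years.size))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        u_inc, u_fat, u_cost = rng.uniform(size=3)
        m_inc = spec.incidence_shock.ppf(u_inc)
        m_fat = spec.fatality_shock.ppf(u_fat)
        m_cost = spec.cost_shock.ppf(u_cost)
        caseload = _iteration_caseload(spec, inputs, m_inc, m_fat)
        eta = rng.standard_normal(years.size - 1)
        w = np.concatenate([[0.0], np.cumsum(eta)])
        factor = np.exp(drift + spec.process_sigma * w)
        annual = caseload * ks * m_cost * factor
        annual_paths[i] = annual
        cum[i] = annual[window].sum()

    cutoff = max_expected_cost_var(cum, spec.alpha)
    per_year = pd.Series(
        [max_expected_cost_var(annual_paths[:, j], spec.alpha)
         for j in range(years.size)],
        index=years,
        name="per_year_var",
    )
    logger.info(
        "scenario %s: V_c = %.2f M pesos over %d iterations",
        spec.name, cutoff / 1e6, spec.n_iterations,
    )
    return VaRResult(
        scenario=spec.name,
        iteration_costs=cum,
        var_cutoff=cutoff,
        level=1.0 - spec.alpha,
        amortized_annual=cutoff / inputs.amortization_years,
        amortization_years=inputs.amortization_years,
        horizon=(int(lo), int(hi)),
        seed=spec.seed,
        n_iterations=spec.n_iterations,
        per_year_var=per_year,
    )


def base_scenario(seed: int = 0, n_iterations: int = 5000, **kw) -> ScenarioSpec:
    """Observed incidence, fatality and costs (all shocks at 1)."""
    return ScenarioSpec(name="base", seed=seed, n_iterations=n_iterations, **kw)


def pessimistic_scenario(seed: int = 0, n_iterations: int = 5000, **kw) -> ScenarioSpec:
    """Incidence and costs up to 10% above observed (median +5%)."""
    shock = ShockSpec.truncated_lognormal(1.0, 1.10, median=1.05)
    return ScenarioSpec(
        name="pessimistic", incidence_shock=shock, cost_shock=shock,
        seed=seed, n_iterations=n_iterations, **kw,
    )


def optimistic_scenario(seed: int = 0, n_iterations: int = 5000, **kw) -> ScenarioSpec:
    """Incidence and costs up to 10% below observed (median −5%)."""
    shock = ShockSpec.truncated_lognormal(0.90, 1.00, median=0.95)
    return ScenarioSpec(
        name="optimistic", incidence_shock=shock, cost_shock=shock,
        seed=seed, n_iterations=n_iterations, **kw,
    )


def default_scenarios(seed: int = 0, n_iterations: int = 5000, **kw) -> dict[str, ScenarioSpec]:
    """The three standard scenarios, sharing one seed for coupled draws."""
    return {
        "base": base_scenario(seed, n_iterations, **kw),
        "pessimistic": pessimistic_scenario(seed, n_iterations, **kw),
        "optimistic": optimistic_scenario(seed, n_iterations, **kw),
    }
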