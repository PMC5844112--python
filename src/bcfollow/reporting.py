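"""Fund-ledger arithmetic, amortization and the end-to-end pipeline.

The sustainability question is answered by simple trust-fund
accounting: end-of-year availability = opening availability +
contributions − commitments; the scenario cut-off :math:`V_c` is
amortized over the 18-year policy horizon (three 6-year federal
administrations) and expressed as a share of the fund's end-2013
availability.  Money is reported in million pesos rounded half-up to
two decimals, percentages to one decimal, with rounding applied only at
this boundary.

The published 2007–2013 fund ledger and the published per-year totals
of the 14-cycle monitoring table ship as reference constants
(:data:`FPGC_LEDGER_2007_2013`, :data:`PUBLISHED_CYCLE_TOTALS`); both
are inputs as printed, including the one 0.30-million inconsistency the
ledger itself carries between end-2012 and opening-2013 availability.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import InputError
from .costing import CostParameters, extension_cost
from .epidemiology import mean_incidence, project_cases, susceptible_population
from .risk_var import ScenarioInputs, default_scenarios, run_scenario
from .survival_cycles import (
    SurvivalConfig,
    mean_fatality,
    prior_monitored_cohorts,
    run_cycles,
)
from .synthetic_data import (
    SyntheticConfig,
    generate_cost_components,
    generate_historical_registry,
    generate_population_frames,
)

__all__ = [
    "FPGC_LEDGER_2007_2013",
    "PUBLISHED_CYCLE_TOTALS",
    "FundLedger",
    "PolicyReport",
    "availability_end",
    "amortized_annual",
    "cost_share",
    "default_config",
    "run_pipeline",
    "PipelineResult",
]

logger = logging.getLogger(__name__)

#: Published FPGC trust ledger, million pesos, as printed (data-as-given:
#: end-2012 availability is 4487.70 while opening-2013 is 4487.40).
FPGC_LEDGER_2007_2013 = pd.DataFrame(
    {
        "year": [2007, 2008, 2009, 2010, 2011, 2012, 2013],
        "availability": [2282.44, 3287.23, 6319.60, 5467.98, 7628.57, 10388.90, 4487.40],
        "contributions": [4035.77, 5687.10, 7057.30, 7284.70, 8649.20, 10872.80, 11674.90],
        "commitments": [2520.94, 2654.77, 7908.90, 5124.11, 5888.87, 16774.00, 9418.80],
        "availability_end": [3797.27, 6319.56, 5468.00, 7628.57, 10388.90, 4487.70, 6743.50],
    }
)

#: Published per-year totals of the 14-cycle monitoring table
#: (diagnosis-aligned columns 2013–2030); they sum to 200,410
#: monitored person-years.
PUBLISHED_CYCLE_TOTALS = pd.Series(
    [2531, 4700, 6567, 8182, 9584, 10808, 11883, 12830, 13671,
     14421, 15094, 15700, 16250, 16750, 13711, 11197, 9121, 7410],
    index=range(2013, 2031),
    name="published_cycle_totals",
)


def _round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (2.675 → 2.68), applied at reporting only."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def availability_end(
    availability: float, contributions: float, commitments: float
) -> float:
    """End-of-year fund availability, million pesos, to 2 decimals."""
    for v in (availability, contributions, commitments):
        if not np.isfinite(v):
            raise InputError("ledger inputs must be finite")
    return _round_half_up(availability + contributions - commitments, 2)


def amortized_annual(cumulative: float, years: int = 18) -> float:
    """Annual amount when ``cumulative`` is amortized over ``years``."""
    if years < 1:
        raise InputError("amortization years must be >= 1")
    return _round_half_up(cumulative / years, 2)


def cost_share(annual: float, reference: float) -> float:
    """Annual amount as a percentage of a reference amount, 1 decimal."""
    if reference <= 0:
        raise InputError("reference amount must be positive")
    return _round_half_up(100.0 * annual / reference, 1)


@dataclass
class FundLedger:
    """Per-year fund ledger (availability, contributions, commitments)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"year", "availability", "contributions", "commitments"}
        if required - set(self.data.columns):
            raise InputError(f"FundLedger requires columns {sorted(required)}")
        self.data = self.data.reset_index(drop=True)

    @classmethod
    def published(cls) -> "FundLedger":
        return cls(FPGC_LEDGER_2007_2013.copy())

    @classmethod
    def read_csv(cls, path: str | Path) -> "FundLedger":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def computed_end(self) -> pd.Series:
        """Recompute end-of-year availability from each year's inputs."""
        return pd.Series(
            [
                availability_end(r.availability, r.contributions, r.commitments)
                for r in self.data.itertuples()
            ],
            index=self.data["year"].to_numpy(),
            name="availability_end",
        )

    def end_availability(self, year: int) -> float:
        row = self.data[self.data["year"] == year]
        if row.empty:
            raise InputError(f"ledger has no year {year}")
        if "availability_end" in row.columns and not row["availability_end"].isna().all():
            return float(row["availability_end"].iloc[0])
        return float(self.computed_end().loc[year])


@dataclass
class PolicyReport:
    """Headline figures for one scenario, in reporting units.

    ``share_of_reference`` divides the amortized annual amount by a
    named reference (by default the fund's end-2013 availability).
    """

    scenario: str
    cumulative_million: float
    amortization_years: int
    annual_million: float
    reference_name: str
    reference_million: float
    share_of_reference_pct: float

    @classmethod
    def from_var(
        cls,
        scenario: str,
        cumulative_pesos: float,
        reference_million: float,
        reference_name: str = "FPGC end-2013 availability",
        amortization_years: int = 18,
    ) -> "PolicyReport":
        cumulative_million = _round_half_up(cumulative_pesos / 1e6, 2)
        annual = amortized_annual(cumulative_million, amortization_years)
        return cls(
            scenario=scenario,
            cumulative_million=cumulative_million,
            amortization_years=amortization_years,
            annual_million=annual,
            reference_name=reference_name,
            reference_million=reference_million,
            share_of_reference_pct=cost_share(annual, reference_million),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_config() -> dict:
    """Default pipeline configuration (synthetic inputs, three scenarios)."""
    return {
        "seed": 0,
        "synthetic": {},
        "survival": {},
        "costing": {"inflation": 0.03},
        "scenarios": {
            "n_iterations": 5000,
            "alpha": 0.05,
            "process_mu": 0.0,
            "process_sigma": 0.10,
        },
        "horizon": [2013, 2026],
        "amortization_years": 18,
    }


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON config file and merge it over the defaults."""
    path = Path(path)
    try:
        loaded = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise InputError(f"malformed config {path}: {exc}") from exc
    if loaded is None:
        loaded = {}
    if not isinstance(loaded, dict):
        raise InputError(f"config {path} must map keys to sections")
    cfg = default_config()
    for key, value in loaded.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


@dataclass
class PipelineResult:
    """All artifacts of a full pipeline run."""

    config: dict
    incidence: object
    fatality: object
    cases: object
    cycle_table: object
    cost_schedule: object
    var_results: dict
    reports: dict
    ledger: FundLedger


def run_pipeline(
    config: dict | str | Path | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Chain every stage: synth → project → cycles → cost → VaR → report.

    ``config`` may be a mapping or a YAML/JSON path; ``seed`` overrides
    the config seed.  With ``outdir`` set, every intermediate artifact
    is written (tidy CSVs, the cycle table, per-iteration audit files
    and a JSON report).  All three scenarios share one seed, coupling
    their draws for comparability.
    """
    if config is None:
        cfg = default_config()
    elif isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        base = default_config()
        for key, value in config.items():
            if isinstance(value, dict) and isinstance(base.get(key), dict):
                base[key].update(value)
            else:
                base[key] = value
        cfg = base
    if seed is not None:
        cfg["seed"] = int(seed)

    syn = SyntheticConfig(seed=int(cfg["seed"]), **cfg.get("synthetic", {}))
    scfg = SurvivalConfig(**cfg.get("survival", {}))
    horizon = tuple(cfg.get("horizon", [2013, 2026]))
    amort = int(cfg.get("amortization_years", 18))

    logger.info("stage synth: seed=%d", syn.seed)
    new_cases_hist, at_risk, deaths, diagnosed = generate_historical_registry(syn)
    projected, shares = generate_population_frames(syn)
    hist_years = new_cases_hist.years

    logger.info("stage project: horizon %s", horizon)
    Io = mean_incidence(new_cases_hist, at_risk, hist_years)
    L = mean_fatality(deaths, diagnosed, hist_years)
    Ps = susceptible_population(projected, shares, horizon)
    priors = prior_monitored_cohorts(diagnosed, L, ref_year=horizon[0])
    cases = project_cases(Io, Ps, priors, horizon=horizon, ref_year=horizon[0])

    logger.info("stage cycles: %d cycles", scfg.n_cycles)
    cycle_table = run_cycles(cases, priors, L, scfg, ref_year=horizon[0])

    params = generate_cost_components(syn)
    params = CostParameters(
        base_year=params.base_year,
        medicines_cost=params.medicines_cost,
        clinical_analysis_cost=params.clinical_analysis_cost,
        inflation=float(cfg.get("costing", {}).get("inflation", params.inflation)),
    )
    logger.info("stage cost: Ks(2013) = %.0f pesos", params.base_unit_cost)
    cost_schedule = extension_cost(cycle_table.totals(), params)

    sc = cfg.get("scenarios", {})
    scenario_kw = {
        k: sc[k] for k in ("alpha", "process_mu", "process_sigma") if k in sc
    }
    specs = default_scenarios(
        seed=int(cfg["seed"]),
        n_iterations=int(sc.get("n_iterations", 5000)),
        **scenario_kw,
    )
    inputs = ScenarioInputs.from_components(
        cases, priors, L, params, scfg,
        cumulative_window=horizon, amortization_years=amort, ref_year=horizon[0],
    )
    var_results = {}
    for name, spec in specs.items():
        logger.info("stage var: scenario %s, %d iterations", name, spec.n_iterations)
        var_results[name] = run_scenario(spec, inputs)

    ledger = FundLedger.published()
    reference = ledger.end_availability(2013)
    reports = {
        name: PolicyReport.from_var(
            name, res.var_cutoff, reference, amortization_years=amort
        )
        for name, res in var_results.items()
    }

    result = PipelineResult(
        config=cfg,
        incidence=Io,
        fatality=L,
        cases=cases,
        cycle_table=cycle_table,
        cost_schedule=cost_schedule,
        var_results=var_results,
        reports=reports,
        ledger=ledger,
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.incidence.to_csv(outdir / "incidence_schedule.csv")
    result.fatality.to_csv(outdir / "fatality_schedule.csv")
    result.cases.to_csv(outdir / "case_matrix.csv")
    result.cycle_table.to_csv(outdir / "cycle_table.csv")
    result.cost_schedule.to_csv(outdir / "cost_schedule.csv")
    result.ledger.to_csv(outdir / "fund_ledger.csv")
    for name, res in result.var_results.items():
        res.to_json(outdir / f"var_{name}.json")
        res.iterations_to_csv(outdir / f"var_{name}_iterations.csv")
    report = {name: rep.to_dict() for name, rep in result.reports.items()}
    (outdir / "policy_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True)
    )
    (outdir / "config_used.json").write_text(
        json.dumps(result.config, indent=2, sort_keys=True, default=str)
    )
    logger.info("artifacts written to %s", outdir)
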