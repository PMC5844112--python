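"""Synthetic registry, population and cost inputs for the pipeline.

No public registry deposit accompanies the analysis, so every input the
downstream stages need — age-specific incidence and case-fatality
schedules, a CONAPO-style population projection, affiliation shares, a
2007–2013 historical registry and per-cycle monitoring cost components —
is generated here with the statistical structure of the population the
model describes:

* incidence confined to ages 20+, concentrated at 50–69 (about 54% of
  implied cases) and 40–79 (about 92%);
* case fatality lowest at ages 20–29 (18.7 per 100,000 diagnosed) and
  rising steeply after midlife, calibrated so that roughly 30% of a
  diagnosis cohort survives the first six post-diagnosis years (one
  treatment year plus five covered monitoring years);
* a 2013 diagnosis cohort of exactly 7841 women;
* a stage mix of roughly 28% (I–IIA), 61% (IIB–III), 9% (IV), kept as
  descriptive metadata only — the cost model applies a single
  monitoring cost to all stages.

All stochastic outputs are driven by ``SyntheticConfig.seed``; the same
config yields byte-identical frames.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import (
    AGE_MAX,
    AGES,
    PER_100K,
    AgeSchedule,
    ConfigurationError,
    PopulationFrame,
)
from .costing import CostParameters

__all__ = [
    "SyntheticConfig",
    "female_age_pyramid",
    "generate_incidence_schedule",
    "generate_fatality_schedule",
    "generate_population_frames",
    "generate_historical_registry",
    "generate_cost_components",
    "write_inputs",
]

logger = logging.getLogger(__name__)

# Shape constants, calibrated once to the documented case-share and
# survival structure (see docs/methods.md).  Incidence: logistic rise in
# the early 40s, plateau through the mid-60s, gaussian decline after.
_INC_RISE_MID = 42.0
_INC_RISE_SCALE = 3.0
_INC_DECLINE_FROM = 66.0
_INC_DECLINE_SD = 11.0
# Fatality: sigmoid from the young-adult floor to an old-age plateau.
_FAT_MID = 55.0
_FAT_SCALE = 7.0

_HIST_YEARS = range(2007, 2014)


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic input generator.

    Attributes
    ----------
    seed
        Seed for all stochastic outputs (registry counts).
    horizon_years
        Inclusive calendar range of the population projection.
    n_women_total
        Affiliated (susceptible) women of all ages in 2013.
    incidence_peak_band
        Age band that should concentrate slightly over half of the
        implied cases (default 50–69).
    fatality_floor
        Case-fatality at ages 20–29, per 100,000 diagnosed per year.
    fatality_peak
        Old-age case-fatality plateau, per 100,000 diagnosed per year.
        The default (32,000) reproduces ≈30% six-year cohort survival.
    cohort_2013_size
        Exact number of diagnoses in the 2013 registry year.
    stage_shares
        Proportions for stages (I–IIA, IIB–III, IV); renormalized to
        sum to one (descriptive metadata only).
    affiliation_share
        Share of the projected female population affiliated to the
        insurer, applied uniformly across ages.
    pop_growth
        Annual growth rate of the projected population.
    incidence_scale
        Global multiplier on the incidence schedule (0 ⇒ no cases).
    medicines_cost, clinical_analysis_cost
        Base-year (2013) monitoring cost components, pesos per
        patient-year.
    """

    seed: int = 0
    horizon_years: tuple[int, int] = (2007, 2030)
    n_women_total: int = 25_000_000
    incidence_peak_band: tuple[int, int] = (50, 69)
    fatality_floor: float = 18.7
    fatality_peak: float = 32_000.0
    cohort_2013_size: int = 7841
    stage_shares: tuple[float, float, float] = (0.28, 0.61, 0.09)
    affiliation_share: float = 0.45
    pop_growth: float = 0.010
    incidence_scale: float = 1.0
    medicines_cost: float = 12_000.0
    clinical_analysis_cost: float = 6_000.0

    def __post_init__(self) -> None:
        lo, hi = self.horizon_years
        if lo > hi:
            raise ConfigurationError("horizon_years must be a nonempty range")
        blo, bhi = self.incidence_peak_band
        if not (0 <= blo < bhi <= AGE_MAX):
            raise ConfigurationError(
                f"incidence_peak_band must satisfy 0 <= lo < hi <= {AGE_MAX}"
            )
        if self.fatality_floor < 0:
            raise ConfigurationError("fatality_floor must be nonnegative")
        if self.fatality_peak < 0:
            raise ConfigurationError("fatality_peak must be nonnegative")
        if self.n_women_total < 0 or self.cohort_2013_size < 0:
            raise ConfigurationError("counts must be nonnegative")
        if any(s < 0 for s in self.stage_shares) or sum(self.stage_shares) <= 0:
            raise ConfigurationError("stage_shares must be nonnegative, not all zero")
        if not 0 <= self.affiliation_share <= 1:
            raise ConfigurationError("affiliation_share must lie in [0, 1]")
        if self.incidence_scale < 0:
            raise ConfigurationError("incidence_scale must be nonnegative")
        if self.medicines_cost < 0 or self.clinical_analysis_cost < 0:
            raise ConfigurationError("cost components must be nonnegative")

    @property
    def stage_distribution(self) -> tuple[float, ...]:
        """Stage shares renormalized to sum to exactly one."""
        total = sum(self.stage_shares)
        return tuple(s / total for s in self.stage_shares)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def female_age_pyramid() -> np.ndarray:
    """Normalized female age distribution (weights over ages 0–100).

    A smooth parametric stand-in for the official projection: flat
    through age 45, declining piecewise-linearly to a small floor at
    100.  Only the product incidence × pyramid matters downstream, so
    the pyramid is deliberately simple.
    """
    w = np.where(
        AGES <= 45, 1.0, np.maximum(1.0 - (AGES - 45) * (0.96 / 55.0), 0.04)
    )
    return w / w.sum()


def _incidence_shape(band: tuple[int, int]) -> np.ndarray:
    """Unnormalized unimodal incidence shape, zero below age 20.

    The rise/plateau/decline anchors shift rigidly with the configured
    peak band relative to the default 50–69.
    """
    shift = (band[0] + band[1]) / 2.0 - 59.5
    rise_mid = _INC_RISE_MID + shift
    decline_from = _INC_DECLINE_FROM + shift
    shape = expit((AGES - rise_mid) / _INC_RISE_SCALE) * np.where(
        AGES <= decline_from,
        1.0,
        np.exp(-0.5 * ((AGES - decline_from) / _INC_DECLINE_SD) ** 2),
    )
    return np.where(AGES < 20, 0.0, shape)


def generate_incidence_schedule(cfg: SyntheticConfig) -> AgeSchedule:
    """Age-specific incidence per 100,000 at-risk women.

    The overall level is anchored so that, applied to the 2013 affiliated
    female population, the schedule implies ``cfg.cohort_2013_size``
    expected diagnoses; the shape places ≈54% of implied cases in the
    peak band and ≥90% at ages 40–79.  Deterministic given the config.
    """
    shape = _incidence_shape(cfg.incidence_peak_band)
    pyramid = female_age_pyramid()
    expected_per_unit = float((shape * pyramid).sum()) * cfg.n_women_total
    if expected_per_unit == 0 or cfg.incidence_scale == 0:
        return AgeSchedule(np.zeros(AGE_MAX + 1), basis="at-risk women")
    level = cfg.cohort_2013_size / expected_per_unit
    frac = cfg.incidence_scale * level * shape
    return AgeSchedule.from_fraction(frac, basis="at-risk women")


def generate_fatality_schedule(cfg: SyntheticConfig) -> AgeSchedule:
    """Age-specific case fatality per 100,000 diagnosed per year.

    Exactly ``cfg.fatality_floor`` at ages below 30; a monotone sigmoid
    rise from age 30 towards the old-age plateau ``cfg.fatality_peak``
    (so rates are non-decreasing from age 60 upward by construction).
    """
    floor = cfg.fatality_floor / PER_100K
    peak = cfg.fatality_peak / PER_100K
    frac = np.full(AGE_MAX + 1, floor)
    older = AGES >= 30
    frac[older] = floor + max(peak - floor, 0.0) * expit(
        (AGES[older] - _FAT_MID) / _FAT_SCALE
    )
    frac = np.clip(frac, 0.0, 1.0)
    return AgeSchedule.from_fraction(frac, basis="diagnosed patients")


def generate_population_frames(
    cfg: SyntheticConfig,
) -> tuple[PopulationFrame, AgeSchedule]:
    """Projected female population by year × age, and affiliation shares.

    The projection grows the 2013 pyramid at ``cfg.pop_growth`` per year
    with a static age structure; affiliation shares are a flat
    ``cfg.affiliation_share`` across ages, expressed as a per-unit
    :class:`AgeSchedule`.  Both are deterministic given the config.
    """
    lo, hi = cfg.horizon_years
    share = cfg.affiliation_share
    pyramid = female_age_pyramid()
    if share > 0:
        base = cfg.n_women_total * pyramid / share
    else:
        base = cfg.n_women_total * pyramid
    years = np.arange(lo, hi + 1)
    growth = (1.0 + cfg.pop_growth) ** (years - 2013)
    wide = pd.DataFrame(np.outer(growth, base), index=years, columns=AGES)
    projected = PopulationFrame.from_matrix(wide, name="projected population")
    shares = AgeSchedule(
        np.full(AGE_MAX + 1, share), basis="projected population", per=1.0
    )
    return projected, shares


def _affiliated_matrix(cfg: SyntheticConfig, years: range) -> pd.DataFrame:
    projected, shares = generate_population_frames(cfg)
    wide = projected.matrix(list(years))
    return wide.mul(shares.fraction, axis=1)


def generate_historical_registry(
    cfg: SyntheticConfig,
) -> tuple[PopulationFrame, PopulationFrame, PopulationFrame, PopulationFrame]:
    """Registry-style counts for 2007–2013: new cases, at-risk, deaths, diagnosed.

    At-risk cells are the affiliated female population.  New-case counts
    are Poisson around incidence × at-risk, except 2013 which is drawn
    multinomially so the diagnosed total equals ``cfg.cohort_2013_size``
    exactly.  Diagnosed counts equal new cases (incident diagnoses);
    deaths are Binomial(diagnosed, fatality), which enforces
    deaths ≤ diagnosed cell-wise.
    """
    rng = np.random.default_rng(cfg.seed)
    inc = generate_incidence_schedule(cfg).fraction
    fat = generate_fatality_schedule(cfg).fraction
    at_risk_wide = _affiliated_matrix(cfg, _HIST_YEARS)

    rows = []
    for year in _HIST_YEARS:
        pop = at_risk_wide.loc[year].to_numpy()
        mean = inc * pop
        if year == 2013:
            if cfg.cohort_2013_size == 0:
                counts = np.zeros(AGE_MAX + 1)
            else:
                weights = mean if mean.sum() > 0 else female_age_pyramid()
                counts = rng.multinomial(
                    cfg.cohort_2013_size, weights / weights.sum()
                ).astype(float)
        else:
            counts = rng.poisson(mean).astype(float)
        counts = np.minimum(counts, np.floor(pop))  # never exceed the at-risk cell
        rows.append(counts)
    new_wide = pd.DataFrame(rows, index=list(_HIST_YEARS), columns=AGES)

    deaths_wide = pd.DataFrame(
        rng.binomial(new_wide.to_numpy().astype(int), fat).astype(float),
        index=list(_HIST_YEARS),
        columns=AGES,
    )

    new_cases = PopulationFrame.from_matrix(new_wide, name="new cases")
    at_risk = PopulationFrame.from_matrix(at_risk_wide, name="population at risk")
    deaths = PopulationFrame.from_matrix(deaths_wide, name="deaths")
    diagnosed = PopulationFrame.from_matrix(new_wide, name="diagnosed cases")
    logger.info(
        "historical registry generated: %d diagnoses in 2013",
        int(new_wide.loc[2013].sum()),
    )
    return new_cases, at_risk, deaths, diagnosed


def generate_cost_components(cfg: SyntheticConfig) -> CostParameters:
    """Base-year monitoring cost components (pesos per patient-year).

    Deterministic given the config; the default total of 18,000
    pesos/patient-year is the documented paper-scale anchor (cumulative
    cost ÷ monitored person-years ≈ 18,000).
    """
    return CostParameters(
        base_year=2013,
        medicines_cost=cfg.medicines_cost,
        clinical_analysis_cost=cfg.clinical_analysis_cost,
    )


def write_inputs(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write every generated input as tidy CSV plus a JSON config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    new_cases, at_risk, deaths, diagnosed = generate_historical_registry(cfg)
    projected, shares = generate_population_frames(cfg)
    paths: dict[str, Path] = {}
    frames = {
        "new_cases": new_cases,
        "at_risk": at_risk,
        "deaths": deaths,
        "diagnosed": diagnosed,
        "projected_population": projected,
    }
    for name, frame in frames.items():
        paths[name] = outdir / f"{name}.csv"
        frame.to_csv(paths[name])
    for name, sched in {
        "incidence_schedule": generate_incidence_schedule(cfg),
        "fatality_schedule": generate_fatality_schedule(cfg),
        "affiliation_shares": shares,
    }.items():
        paths[name] = outdir / f"{name}.csv"
        sched.to_csv(paths[name])
    params = generate_cost_components(cfg)
    paths["config"] = outdir / "config_echo.json"
    echo = {
        "config": cfg.to_dict(),
        "stage_distribution": cfg.stage_distribution,
        "cost_components": {
            "base_year": params.base_year,
            "medicines_cost": params.medicines_cost,
            "clinical_analysis_cost": params.clinical_analysis_cost,
            "inflation": params.inflation,
        },
    }
    paths["config"].write_text(json.dumps(echo, indent=2, sort_keys=True))
    return paths
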