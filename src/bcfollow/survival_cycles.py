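"""Case fatality, survivors and the extended-monitoring cycle table.

A diagnosis cohort is depleted annually by the age-specific case
fatality :math:`L_e` (each woman ages one year per cycle, so she moves
along the schedule), giving survivors

.. math:: S_{i,e} = C_{i,e} (1 - L_e).

After one treatment year plus five covered monitoring years a cohort
diagnosed in year *d* outlives its financed follow-up and enters the
*extended-monitoring* caseload, where it remains — further depleted
every year — through the end of the reporting horizon.  Fourteen such
cohorts (diagnosed 2013–2026) plus the surviving pre-2013 cohorts make
up the cycle table whose per-year totals are the caseload priced by the
costing stage.

Column convention
-----------------
The cycle table's columns carry *diagnosis-aligned* labels: the column
labelled ``c`` holds each cohort's survivor count observed in calendar
year ``c + offset`` (offset = treatment + covered monitoring years, 6
by default).  Under this labelling cycle 1 (the 2013 cohort) shows its
entry count — survivors of six depletion years, realized in calendar
2019 — in the 2013 column, and totals rise while new cohorts enter
(through 2026) then decline.  ``MonitoringCycleTable.calendar_years``
exposes the realized-calendar labelling of the same columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    AGE_MAX,
    AGES,
    AgeSchedule,
    CaseMatrix,
    ConfigurationError,
    InputError,
    PopulationFrame,
)
from .epidemiology import _mean_ratio_schedule

__all__ = [
    "SurvivalConfig",
    "MonitoringCycleTable",
    "mean_fatality",
    "survivors",
    "survival_factors",
    "prior_monitored_cohorts",
    "run_cycles",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalConfig:
    """Timing parameters of the monitoring recursion.

    ``treatment_years`` + ``covered_monitoring_years`` is the financed
    follow-up window (default 1 + 5); ``n_cycles`` cohorts enter the
    extended caseload (default 14, diagnoses 2013–2026); ``last_year``
    is the last diagnosis-aligned column of the cycle table (default
    2030, i.e. realized calendar year 2036).
    """

    treatment_years: int = 1
    covered_monitoring_years: int = 5
    n_cycles: int = 14
    last_year: int = 2030

    def __post_init__(self) -> None:
        if min(
            self.treatment_years,
            self.covered_monitoring_years,
            self.n_cycles,
            self.last_year,
        ) <= 0:
            raise ConfigurationError("SurvivalConfig fields must be positive")

    @property
    def offset(self) -> int:
        """Years from diagnosis to extended-monitoring entry."""
        return self.treatment_years + self.covered_monitoring_years


@dataclass
class MonitoringCycleTable:
    """Survivors requiring extended monitoring, by cycle × column year.

    ``data`` is indexed by cycle number (1–14 for the entering cohorts;
    zero and negative labels for surviving pre-2013 cohorts) with
    diagnosis-aligned year columns; cells before a cohort's entry are
    NaN.  The totals row is the caseload priced downstream.
    """

    data: pd.DataFrame
    offset: int = 6

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise InputError("cycle table cells must be nonnegative")
        for _, row in self.data.iterrows():
            active = row.dropna().to_numpy()
            if active.size and np.any(np.diff(active) > 1e-9 * np.abs(active[:-1])):
                raise InputError("survivors must be non-increasing within a cycle")

    @property
    def years(self) -> list[int]:
        return [int(c) for c in self.data.columns]

    @property
    def calendar_years(self) -> list[int]:
        """Realized calendar year of each column (label + offset)."""
        return [c + self.offset for c in self.years]

    def totals(self) -> pd.Series:
        """Caseload per column year (sum over all active cohorts)."""
        return self.data.sum(axis=0, skipna=True)

    def to_csv(self, path, labeling: str = "diagnosis") -> None:
        """Write the cycle-row × year-column layout with a totals row."""
        if labeling not in ("diagnosis", "entry"):
            raise InputError("labeling must be 'diagnosis' or 'entry'")
        out = self.data.copy()
        if labeling == "entry":
            out.columns = self.calendar_years
        out.loc["Total"] = out.sum(axis=0, skipna=True)
        out.rename_axis(index="cycle", columns="year").to_csv(path)


def mean_fatality(
    deaths: PopulationFrame,
    diagnosed: PopulationFrame,
    years: list[int],
) -> AgeSchedule:
    """Average case fatality per age: mean over years of deaths/diagnosed.

    Raises :class:`InputError` if any cell has more deaths than
    diagnoses.  Returned per 100,000 diagnosed; ``.fraction`` gives the
    per-patient-year probabilities in [0, 1].
    """
    years = sorted(int(y) for y in years)
    m = deaths.matrix(years).to_numpy()
    d = diagnosed.matrix(years).to_numpy()
    if (m > d).any():
        yi, ai = np.nonzero(m > d)
        raise InputError(
            f"deaths exceed diagnosed at year {years[yi[0]]}, age {int(AGES[ai[0]])}"
        )
    frac = _mean_ratio_schedule(
        deaths, diagnosed, years, basis="diagnosed patients", what="mean_fatality"
    )
    return AgeSchedule.from_fraction(frac, basis="diagnosed patients")


def survivors(cases: CaseMatrix, L: AgeSchedule) -> CaseMatrix:
    """Apply one year of fatality: S = C (1 − L), cell-wise by age."""
    frac = L.fraction
    if np.any(frac > 1):
        raise InputError("fatality fractions must not exceed 1")
    return CaseMatrix(cases=cases.cases.mul(1.0 - frac, axis=1))


def survival_factors(l_frac: np.ndarray, max_years: int) -> np.ndarray:
    """Multi-year survival table G[a, m] = ∏_{t<m} (1 − l[a+t]).

    A woman aged ``a`` today survives the next ``m`` annual cycles with
    probability ``G[a, m]``, aging one year per cycle; fatality beyond
    age 100 is held at the age-100 value.
    """
    l_pad = np.concatenate(
        [np.asarray(l_frac, float), np.full(max_years + 1, float(l_frac[-1]))]
    )
    G = np.ones((AGE_MAX + 1, max_years + 1))
    for m in range(1, max_years + 1):
        G[:, m] = G[:, m - 1] * (1.0 - l_pad[AGES + m - 1])
    return G


def prior_monitored_cohorts(
    diagnosed: PopulationFrame,
    L: AgeSchedule,
    ref_year: int = 2013,
    cohorts: list[int] | None = None,
) -> PopulationFrame:
    """Cohorts diagnosed before ``ref_year`` still monitored at ``ref_year``.

    For each diagnosis cohort *j* the registry counts are depleted
    ``ref_year − j`` annual cycles and shifted to their age as of
    ``ref_year`` (the open age-100 bin absorbs older survivors).
    Returned as a tidy frame whose ``year`` column is the diagnosis
    cohort and whose ``age`` column is age at ``ref_year``.
    """
    if cohorts is None:
        cohorts = [y for y in diagnosed.years if y < ref_year]
    if not cohorts:
        raise InputError("no prior cohorts before the reference year")
    wide = diagnosed.matrix(sorted(cohorts), fill=0.0)
    max_m = max(ref_year - min(cohorts), 1)
    G = survival_factors(L.fraction, max_m)
    rows = {}
    for j in sorted(cohorts):
        m = ref_year - j
        surv = wide.loc[j].to_numpy() * G[:, m]
        aged = np.zeros(AGE_MAX + 1)
        if m == 0:
            aged = surv
        else:
            aged[m:] = surv[:-m]
            aged[AGE_MAX] += surv[AGE_MAX - m + 1:].sum()
        rows[j] = aged
    out = pd.DataFrame(rows).T
    out.columns = AGES
    return PopulationFrame.from_matrix(out, name="prior monitored cohorts")


def run_cycles(
    new_cases: CaseMatrix,
    prior_cohorts: PopulationFrame | None,
    L: AgeSchedule,
    cfg: SurvivalConfig = SurvivalConfig(),
    ref_year: int | None = None,
) -> MonitoringCycleTable:
    """Run the extended-monitoring recursion over all cohorts.

    Cycle *k* is the cohort diagnosed in the *k*-th year of
    ``new_cases`` (2013 + k − 1 by default); it is depleted annually by
    the age-specific fatality from the diagnosis year onward and appears
    in the table from its diagnosis-aligned column (entry = offset
    depletion years) through ``cfg.last_year``.  ``prior_cohorts`` — the
    output of :func:`prior_monitored_cohorts`, stocks as of ``ref_year``
    — are active in every column, further depleted to each column's
    realized calendar year.
    """
    frac = L.fraction
    if np.any(frac > 1):
        raise InputError("fatality fractions must not exceed 1")
    new = new_cases.incident()
    cohort_years = sorted(int(y) for y in new.index)
    if not cohort_years:
        raise InputError("new_cases covers no cohort years")
    first = cohort_years[0]
    if ref_year is None:
        ref_year = first
    cohort_years = cohort_years[: cfg.n_cycles]
    cols = list(range(first, cfg.last_year + 1))
    max_m = cfg.last_year + cfg.offset - min(first, ref_year)
    G = survival_factors(frac, max_m)

    rows: dict[int, np.ndarray] = {}
    if prior_cohorts is not None and not prior_cohorts.data.empty:
        prior_wide = prior_cohorts.matrix(fill=0.0)
        for j in sorted(int(y) for y in prior_wide.index):
            n = prior_wide.loc[j].to_numpy()
            ms = np.array([c + cfg.offset - ref_year for c in cols])
            rows[j - first + 1] = n @ G[:, ms]
    for d in cohort_years:
        if d > cfg.last_year:
            logger.info("cohort %d enters after last_year %d; excluded", d, cfg.last_year)
            continue
        n = new.loc[d].to_numpy()
        active = [c for c in cols if c >= d]
        ms = np.array([c + cfg.offset - d for c in active])
        row = np.full(len(cols), np.nan)
        row[len(cols) - len(active):] = n @ G[:, ms]
        rows[d - first + 1] = row

    data = pd.DataFrame(rows).T
    data.columns = cols
    data = data.sort_index()
    data.index.name = "cycle"
    table = MonitoringCycleTable(data=data, offset=cfg.offset)
    logger.info(
        "cycle table built: %d cohorts, caseload %.0f in %d",
        len(rows), float(table.totals().iloc[-1]), cols[-1],
    )
    return table
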