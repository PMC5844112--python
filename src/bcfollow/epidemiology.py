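"""Incidence estimation and case projection.

The projection follows the registry-based accounting

.. math::

    Io_e = \\frac{1}{n} \\sum_k \\frac{Cn_{k,e}}{Pr_{k,e}}, \\qquad
    Ps_{i,e} = PC_{i,e} \\, PA_{2013,e}, \\qquad
    C_{i,e} = Io_e \\, Ps_{i,e} + \\sum_j Cs_{j,e},

where :math:`Io_e` is the average observed incidence at age *e* over
the historical years *k*, :math:`Ps` the susceptible (affiliated)
population obtained by applying the 2013 affiliation shares to the
projected population, and :math:`Cs_{j,e}` the cohorts diagnosed in
earlier years *j* that are still under monitoring (carried forward by
aging, with depletion handled downstream by the survival stage).

A literal variant in which the incidence multiplies the carried cases
as well, :math:`C = Io (Ps + \\sum Cs)`, is available behind
``literal_bracket=True``; the default additive accounting is the one
that matches prevalence = new cases + monitored prior cases.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    AGE_MAX,
    AGES,
    AgeSchedule,
    CaseMatrix,
    InputError,
    PopulationFrame,
)

__all__ = [
    "AgeSchedule",
    "PopulationFrame",
    "CaseMatrix",
    "mean_incidence",
    "susceptible_population",
    "project_cases",
]

logger = logging.getLogger(__name__)

DEFAULT_HORIZON = (2013, 2026)


def _mean_ratio_schedule(
    numer: PopulationFrame,
    denom: PopulationFrame,
    years: list[int],
    basis: str,
    what: str,
) -> np.ndarray:
    """Per-age mean over years of cell-wise ratios numer/denom.

    Cells with a zero denominator contribute a zero ratio when the
    numerator is also zero (keeping ``n`` constant per age) and raise
    :class:`InputError` otherwise.
    """
    years = sorted(int(y) for y in years)
    if not years:
        raise InputError(f"{what}: empty year set")
    num = numer.matrix(years).to_numpy()
    den = denom.matrix(years).to_numpy()
    bad = (den == 0) & (num > 0)
    if bad.any():
        yi, ai = np.nonzero(bad)
        raise InputError(
            f"{what}: undefined rate (zero denominator with positive numerator) "
            f"at year {years[yi[0]]}, age {int(AGES[ai[0]])}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return ratio.mean(axis=0)


def mean_incidence(
    new_cases: PopulationFrame,
    at_risk: PopulationFrame,
    years: list[int],
) -> AgeSchedule:
    """Average observed incidence per age over the given registry years.

    Returns the schedule scaled per 100,000 at-risk women;
    ``AgeSchedule.fraction`` recovers the per-unit rates.
    """
    frac = _mean_ratio_schedule(
        new_cases, at_risk, years, basis="at-risk women", what="mean_incidence"
    )
    return AgeSchedule.from_fraction(frac, basis="at-risk women")


def susceptible_population(
    projected: PopulationFrame,
    affiliation_shares: AgeSchedule,
    horizon: tuple[int, int] = DEFAULT_HORIZON,
) -> PopulationFrame:
    """Susceptible population Ps = projected population × affiliation share.

    Shares are per-age proportions in [0, 1] (reference-year affiliation
    structure held fixed over the horizon), so Ps ≤ PC cell-wise.
    """
    share = affiliation_shares.fraction
    if np.any(share < 0) or np.any(share > 1):
        raise InputError("affiliation shares must lie in [0, 1]")
    years = list(range(horizon[0], horizon[1] + 1))
    wide = projected.matrix(years).mul(share, axis=1)
    return PopulationFrame.from_matrix(wide, name="susceptible population")


def _carried_matrix(
    prior_monitored: PopulationFrame | None,
    years: list[int],
    ref_year: int,
) -> pd.DataFrame:
    """Age prior-cohort stocks forward one year of age per calendar year.

    ``prior_monitored`` holds, per diagnosis cohort (its ``year``
    column), the women still under monitoring at ``ref_year`` with their
    ``age`` as of ``ref_year``.  Survival depletion is applied by the
    survival stage, not here; ages beyond 100 accumulate in the open
    age-100 bin.
    """
    carried = pd.DataFrame(0.0, index=years, columns=AGES)
    if prior_monitored is None or prior_monitored.data.empty:
        return carried
    base = prior_monitored.matrix(fill=0.0).sum(axis=0).to_numpy()  # over cohorts
    for year in years:
        shift = year - ref_year
        aged = np.zeros(AGE_MAX + 1)
        if shift == 0:
            aged = base.copy()
        else:
            aged[shift:] = base[:-shift] if shift <= AGE_MAX else 0.0
            aged[AGE_MAX] += base[max(AGE_MAX - shift + 1, 0):].sum()
        carried.loc[year] = aged
    return carried


def project_cases(
    Io: AgeSchedule,
    Ps: PopulationFrame,
    prior_monitored: PopulationFrame | None = None,
    horizon: tuple[int, int] = DEFAULT_HORIZON,
    ref_year: int = 2013,
    literal_bracket: bool = False,
) -> CaseMatrix:
    """Project served cases per year and age over the horizon.

    The default accounting is ``C = Io·Ps + carried`` (new cases plus
    prior cohorts still monitored); ``literal_bracket=True`` switches to
    the multiplicative form ``C = Io·(Ps + carried)``.  The incident
    component stays retrievable via ``CaseMatrix.incident()``.
    """
    if horizon[0] < ref_year:
        raise InputError(
            f"projection horizon starts {horizon[0]}, before the reference "
            f"year {ref_year}"
        )
    if horizon[0] > horizon[1]:
        raise InputError("empty projection horizon")
    years = list(range(horizon[0], horizon[1] + 1))
    ps = Ps.matrix(years)
    frac = Io.fraction
    new = ps.mul(frac, axis=1)
    carried = _carried_matrix(prior_monitored, years, ref_year)
    if literal_bracket:
        total = (ps + carried).mul(frac, axis=1)
        new = total
        carried = pd.DataFrame(0.0, index=years, columns=AGES)
    else:
        total = new + carried
    logger.info(
        "projected cases %d-%d: %.0f in %d, %.0f in %d",
        horizon[0], horizon[1],
        float(total.iloc[0].sum()), years[0],
        float(total.iloc[-1].sum()), years[-1],
    )
    return CaseMatrix(cases=total, new_cases=new, carried=carried)
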