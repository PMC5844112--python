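"""Micro-costing of the monitoring extension.

The per-patient-year monitoring cost is the sum of its itemized
components (medicines + clinical analyses) inflated 3% annually from
the 2013 base year,

.. math:: Ks_i = (M_0 + AC_0)(1 + \\pi)^{i - i_0},

and the annual cost of the extension is the caseload times the unit
cost, :math:`C_i = Cs_i \\, Ks_i`.  Money is carried in pesos
internally; the reporting stage converts to millions at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ConfigurationError, InputError

__all__ = [
    "CostParameters",
    "CostSchedule",
    "monitoring_unit_cost",
    "extension_cost",
]


@dataclass(frozen=True)
class CostParameters:
    """Base-year monitoring cost components and the inflation rate.

    The default component total of 18,000 pesos per patient-year is the
    documented scale anchor: the reported cumulative extension cost
    divided by the ≈200,000 monitored person-years implies roughly
    18,000 pesos per patient-year at 2013 prices.
    """

    base_year: int = 2013
    medicines_cost: float = 12_000.0
    clinical_analysis_cost: float = 6_000.0
    inflation: float = 0.03

    def __post_init__(self) -> None:
        if self.medicines_cost < 0 or self.clinical_analysis_cost < 0:
            raise ConfigurationError("cost components must be nonnegative")
        if self.inflation < 0:
            raise ConfigurationError("inflation must be nonnegative")

    @property
    def base_unit_cost(self) -> float:
        """Ks at the base year: medicines + clinical analyses."""
        return self.medicines_cost + self.clinical_analysis_cost


@dataclass
class CostSchedule:
    """Per-year caseload, unit cost and total cost of the extension."""

    data: pd.DataFrame  # columns: year, caseload, unit_cost, total

    def __post_init__(self) -> None:
        required = {"year", "caseload", "unit_cost", "total"}
        if required - set(self.data.columns):
            raise InputError(f"CostSchedule requires columns {sorted(required)}")
        if (self.data[["caseload", "unit_cost", "total"]].to_numpy() < 0).any():
            raise InputError("CostSchedule values must be nonnegative")
        expected = self.data["caseload"] * self.data["unit_cost"]
        if not np.array_equal(expected.to_numpy(), self.data["total"].to_numpy()):
            raise InputError("total must equal caseload × unit_cost exactly")

    @property
    def years(self) -> list[int]:
        return self.data["year"].astype(int).tolist()

    @property
    def annual_totals(self) -> pd.Series:
        return self.data.set_index("year")["total"]

    def cumulative(self, through: int | None = None) -> float:
        """Cumulative cost in pesos, optionally truncated at a year."""
        totals = self.annual_totals
        if through is not None:
            totals = totals.loc[:through]
        return float(totals.sum())

    @property
    def cumulative_series(self) -> pd.Series:
        return self.annual_totals.cumsum()

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def monitoring_unit_cost(params: CostParameters, year: int) -> float:
    """Per-patient-year monitoring cost Ks at ``year``, in pesos."""
    if year < params.base_year:
        raise InputError(
            f"year {year} precedes the costing base year {params.base_year}"
        )
    return params.base_unit_cost * (1.0 + params.inflation) ** (year - params.base_year)


def extension_cost(caseload: pd.Series, params: CostParameters) -> CostSchedule:
    """Annual extension cost C_i = Cs_i × Ks_i for a per-year caseload.

    ``caseload`` maps year → patients under extended monitoring (the
    totals row of the cycle table).
    """
    years = [int(y) for y in caseload.index]
    unit = np.array([monitoring_unit_cost(params, y) for y in years])
    cs = caseload.to_numpy(dtype=float)
    data = pd.DataFrame(
        {"year": years, "caseload": cs, "unit_cost": unit, "total": cs * unit}
    )
    return CostSchedule(data=data)
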