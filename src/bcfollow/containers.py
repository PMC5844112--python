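"""Core data containers shared across the pipeline.

Three structures carry almost all state between stages:

``AgeSchedule``
    A rate for every single year of age 0–100, with its denominator
    semantics (per 100,000 at-risk women for incidence, per 100,000
    diagnosed patients for case fatality, per-unit for affiliation
    shares) carried as metadata.

``PopulationFrame``
    A tidy ``(year, age, value)`` table — the common dialect for
    registry counts, population projections and prior-cohort stocks.
    All CSV interchange between stages uses this layout.

``CaseMatrix``
    Expected cases indexed by calendar year × age, optionally keeping
    the incident (new-case) and carried (previously diagnosed, still
    monitored) components separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AGE_MAX",
    "AGES",
    "PER_100K",
    "BcfollowError",
    "ConfigurationError",
    "InputError",
    "AgeSchedule",
    "PopulationFrame",
    "CaseMatrix",
]

AGE_MAX = 100
AGES = np.arange(AGE_MAX + 1)
PER_100K = 100_000.0


class BcfollowError(ValueError):
    """Base class for all validation errors raised by this package."""


class ConfigurationError(BcfollowError):
    """An invalid configuration value (bad age band, negative rate, ...)."""


class InputError(BcfollowError):
    """Invalid or inconsistent input data (missing cell, zero denominator, ...)."""


@dataclass
class AgeSchedule:
    """A per-age rate over the closed age range 0–100.

    Parameters
    ----------
    rate
        Array of length 101; ``rate[a]`` is the rate at exact age ``a``,
        expressed per ``per`` persons of the stated ``basis``.
    basis
        Denominator semantics, e.g. ``"at-risk women"`` for incidence,
        ``"diagnosed patients"`` for case fatality, ``"projected
        population"`` for affiliation shares.
    per
        Denominator scale. 100,000 for epidemiological rates; 1.0 for
        proportions such as affiliation shares.
    """

    rate: np.ndarray
    basis: str = "at-risk women"
    per: float = PER_100K

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=float)
        if self.rate.shape != (AGE_MAX + 1,):
            raise InputError(
                f"AgeSchedule requires one rate per age 0-{AGE_MAX}; "
                f"got shape {self.rate.shape}"
            )
        if not np.all(np.isfinite(self.rate)):
            raise InputError("AgeSchedule rates must be finite")
        if np.any(self.rate < 0):
            raise InputError("AgeSchedule rates must be nonnegative")
        if self.per <= 0:
            raise InputError("AgeSchedule scale `per` must be positive")

    @property
    def fraction(self) -> np.ndarray:
        """Rates as plain per-unit fractions (rate / per)."""
        return self.rate / self.per

    @classmethod
    def from_fraction(
        cls, frac: np.ndarray, basis: str = "at-risk women", per: float = PER_100K
    ) -> "AgeSchedule":
        """Build from per-unit fractions, storing them scaled to ``per``."""
        return cls(rate=np.asarray(frac, dtype=float) * per, basis=basis, per=per)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": AGES, "rate": self.rate})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(
        cls, path: str | Path, basis: str = "at-risk women", per: float = PER_100K
    ) -> "AgeSchedule":
        df = pd.read_csv(path)
        rate = (
            df.set_index("age")["rate"].reindex(AGES, fill_value=0.0).to_numpy(float)
        )
        return cls(rate=rate, basis=basis, per=per)


@dataclass
class PopulationFrame:
    """A tidy ``(year, age, value)`` table with one cell per pair.

    Used for population projections (counts of women), registry counts
    (new cases, deaths, diagnosed, at-risk), and prior-cohort stocks.
    """

    data: pd.DataFrame
    name: str = "population"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = {"year", "age", "value"} - set(df.columns)
        if missing:
            raise InputError(f"PopulationFrame missing columns: {sorted(missing)}")
        df = df[["year", "age", "value"]].copy()
        df["year"] = df["year"].astype(int)
        df["age"] = df["age"].astype(int)
        df["value"] = df["value"].astype(float)
        if df.duplicated(["year", "age"]).any():
            raise InputError(f"duplicate (year, age) cells in {self.name!r}")
        if not np.all(np.isfinite(df["value"])):
            raise InputError(f"non-finite values in {self.name!r}")
        if (df["value"] < 0).any():
            raise InputError(f"negative counts in {self.name!r}")
        if (df["age"] < 0).any() or (df["age"] > AGE_MAX).any():
            raise InputError(f"ages outside 0-{AGE_MAX} in {self.name!r}")
        self.data = df.sort_values(["year", "age"]).reset_index(drop=True)

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())

    def matrix(
        self, years: list[int] | None = None, fill: float | None = None
    ) -> pd.DataFrame:
        """Pivot to a dense year × age (0–100) matrix of floats.

        Ages never observed in the frame are filled with 0.  A cell
        present for some ages of a year but missing for others raises
        :class:`InputError` for registry-style frames (``fill=None``);
        sparse frames such as prior-cohort stocks pass ``fill=0.0`` to
        treat absent cells as empty.
        """
        df = self.data
        if years is not None:
            absent = set(years) - set(df["year"].unique())
            if absent:
                raise InputError(
                    f"{self.name!r} is missing year(s) {sorted(absent)}"
                )
            df = df[df["year"].isin(years)]
        wide = df.pivot(index="year", columns="age", values="value")
        if wide.isna().any().any():
            if fill is None:
                raise InputError(f"missing (year, age) cell in {self.name!r}")
            wide = wide.fillna(fill)
        wide = wide.reindex(columns=AGES, fill_value=0.0)
        wide.columns = AGES
        return wide.astype(float)

    @classmethod
    def from_matrix(cls, wide: pd.DataFrame, name: str = "population") -> "PopulationFrame":
        tidy = (
            wide.rename_axis(index="year", columns="age")
            .stack()
            .rename("value")
            .reset_index()
        )
        return cls(tidy, name=name)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, name: str | None = None) -> "PopulationFrame":
        return cls(pd.read_csv(path), name=name or Path(path).stem)


@dataclass
class CaseMatrix:
    """Expected (served) cases by calendar year × age.

    ``cases`` always holds the total served caseload.  When produced by
    the projection stage the incident component (incidence × susceptible
    population) and the carried component (cohorts diagnosed earlier and
    still under monitoring) are retained separately.
    """

    cases: pd.DataFrame
    new_cases: pd.DataFrame | None = field(default=None, repr=False)
    carried: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.cases = self.cases.astype(float)
        if (self.cases.to_numpy() < 0).any():
            raise InputError("CaseMatrix cells must be nonnegative")

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.cases.index]

    def incident(self) -> pd.DataFrame:
        """The new-case component (falls back to the total if unsplit)."""
        return self.new_cases if self.new_cases is not None else self.cases

    def total_by_year(self) -> pd.Series:
        return self.cases.sum(axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.cases.rename_axis(index="year", columns="age").to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "CaseMatrix":
        wide = pd.read_csv(path, index_col="year")
        wide.columns = wide.columns.astype(int)
        return cls(cases=wide)
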