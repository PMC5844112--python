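import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bcfollow.containers import AGES, AgeSchedule, CaseMatrix, PopulationFrame
from bcfollow.reporting import run_pipeline
from bcfollow.synthetic_data import SyntheticConfig, generate_historical_registry

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def tidy_frame(cells, name="frame"):
    """Build a PopulationFrame from {(year, age): value} cells."""
    rows = [{"year": y, "age": a, "value": v} for (y, a), v in cells.items()]
    return PopulationFrame(pd.DataFrame(rows), name=name)


def schedule_from(values, basis="at-risk women", per=100_000.0):
    """AgeSchedule with given per-unit fractions at {age: frac}, 0 elsewhere."""
    frac = np.zeros(AGES.size)
    for age, v in values.items():
        frac[age] = v
    return AgeSchedule.from_fraction(frac, basis=basis, per=per)


def flat_schedule(frac, basis="diagnosed patients"):
    return AgeSchedule.from_fraction(np.full(AGES.size, frac), basis=basis)


def single_cohort(year, age, count):
    """CaseMatrix with one cohort of `count` women aged `age` in `year`."""
    wide = pd.DataFrame(0.0, index=[year], columns=AGES)
    wide.loc[year, age] = count
    return CaseMatrix(cases=wide)


@pytest.fixture(scope="session")
def default_cfg():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def registry(default_cfg):
    """(new_cases, at_risk, deaths, diagnosed) for the default config."""
    return generate_historical_registry(default_cfg)


@pytest.fixture(scope="session")
def pipeline_small():
    """A full pipeline run with a reduced Monte-Carlo budget."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline({"seed": 3, "scenarios": {"n_iterations": 300}})
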