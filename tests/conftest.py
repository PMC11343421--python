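import pathlib
import sys

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(pathlib.Path(__file__).parent))

import hfcua
from hfcua import parameters as par
from hfcua.parameters import (ALIVE_STATES, ARMS, PERIODS, LifeTable,
                              load_parameters, require_valid)

FIXTURE_DIR = (pathlib.Path(hfcua.__file__).parent / "data" /
               "synthetic_basecase")


@pytest.fixture(scope="session")
def base_bundle():
    """The packaged calibrated synthetic base case (treat as read-only)."""
    return require_valid(load_parameters(FIXTURE_DIR))


@pytest.fixture()
def bundle(base_bundle):
    """A private, mutable copy of the base case."""
    return base_bundle.copy()


@pytest.fixture(scope="session")
def short_bundle(base_bundle):
    """Base case truncated to a 5-year horizon (read-only)."""
    b = base_bundle.copy()
    b.economics.horizon = 60
    return b


def zero_life_table(max_age: int = 130) -> LifeTable:
    """A life table with no background mortality, for closed-form checks."""
    ages = np.arange(0, max_age + 1)
    rows = [pd.DataFrame({"age": ages, "sex": sex, "annual_qx": 0.0,
                          "cv_share": 0.5})
            for sex in ("male", "female")]
    return LifeTable(pd.concat(rows, ignore_index=True),
                     sex_mix={"male": 0.55, "female": 0.45})


def make_deathless(b, horizon=12, identity_matrices=True):
    """Disable mortality/discontinuation on a bundle copy in place."""
    b.cv_death = par.SurvivalSpec(family="exponential", intercept=-80.0)
    b.all_cause_death = par.SurvivalSpec(family="exponential", intercept=-80.0)
    b.discontinuation = None
    b.life_table = zero_life_table()
    b.economics.horizon = horizon
    b.economics.max_age = 130.0
    if identity_matrices:
        for arm in ARMS:
            for period in PERIODS:
                b.transitions.matrices[(arm, period)] = np.eye(4)
    return b


def null_treatment_effects(b):
    """Make the two arms clinically identical except for drug cost."""
    b.hhf.treatment_coef = 0.0
    b.cv_death.treatment_coef = 0.0
    b.all_cause_death.treatment_coef = 0.0
    b.discontinuation = None
    for period in PERIODS:
        b.transitions.matrices[("EPG_SOC", period)] = \
            b.transitions.matrices[("SOC", period)].copy()
    for ev in b.adverse_events.events.values():
        ev.monthly_rate["EPG_SOC"] = ev.monthly_rate["SOC"]
    return b
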