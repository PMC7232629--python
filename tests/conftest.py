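import numpy as np
import pandas as pd
import pytest

from wardstaff.config import MultiplierSet
from wardstaff.glmm import ModelSpec, fit_glmm
from wardstaff.pipeline import prepare_model_table
from wardstaff.simulate import FleetConfig, generate_dataset

#: canonical seed for the default-scale study fixtures
DEFAULT_SEED = 0


@pytest.fixture(scope="session")
def multipliers() -> MultiplierSet:
    return MultiplierSet()


@pytest.fixture(scope="session")
def default_dataset() -> dict:
    """The default study-scale synthetic fleet (4 hospitals x 20 units x 365 days)."""
    d = generate_dataset(seed=DEFAULT_SEED)
    d["linked"] = prepare_model_table(d)
    return d


@pytest.fixture(scope="session")
def default_fits(default_dataset) -> dict:
    """The three fully adjusted adequacy fits on the default fleet."""
    return {
        outcome: fit_glmm(ModelSpec(outcome=outcome), default_dataset["linked"])
        for outcome in ("enough_staff", "care_left_undone", "breaks_missed")
    }


@pytest.fixture(scope="session")
def small_dataset() -> dict:
    """A cheap fleet for plumbing tests: 2 hospitals x 6 units x 120 days."""
    d = generate_dataset(
        config=FleetConfig(n_hospitals=2, units_per_hospital=6, days=120),
        seed=DEFAULT_SEED,
    )
    d["linked"] = prepare_model_table(d)
    return d
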