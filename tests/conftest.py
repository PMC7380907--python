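import numpy as np
import pandas as pd
import pytest

from egonet import io_cohort
from egonet.io_cohort import (
    CONFOUNDER_COLUMNS,
    CSSRS_COLUMN,
    ID_COLUMN,
    SIS_COLUMNS,
    CohortTable,
)
from egonet.synthetic_data import GeneratorConfig, generate_cohort


def make_cohort_df(n, rng, missing_cells=()):
    """Small hand-rolled cohort frame; ``missing_cells`` are (row, col) pairs."""
    df = pd.DataFrame({ID_COLUMN: [f"S{i}" for i in range(n)]})
    for col in SIS_COLUMNS:
        df[col] = rng.integers(0, 3, n).astype(float)
    defaults = {
        "sex": lambda: rng.integers(1, 3, n),
        "age": lambda: rng.integers(18, 90, n),
        "marital_status": lambda: rng.integers(1, 7, n),
        "religion": lambda: rng.integers(1, 6, n),
        "monthly_income": lambda: rng.integers(100, 5000, n) * 1000,
        "living_status": lambda: rng.integers(1, 5, n),
        "education": lambda: rng.integers(1, 6, n),
        "urbanicity": lambda: rng.integers(1, 4, n),
        "er_visit_date": lambda: 2013.0 + rng.integers(120, 300, n) / 366,
        "weekend_visit": lambda: rng.integers(1, 3, n),
        "er_visit_time": lambda: rng.integers(0, 24, n),
        "admission_route": lambda: rng.integers(1, 5, n),
        "admission_transport": lambda: rng.integers(1, 6, n),
        "discharge_date": lambda: 2013.5 + rng.integers(0, 100, n) / 366,
    }
    for col in CONFOUNDER_COLUMNS:
        df[col] = np.round(defaults[col](), 3).astype(float)
    df[CSSRS_COLUMN] = rng.integers(1, 7, n).astype(float)
    for row, col in missing_cells:
        df.loc[row, col] = np.nan
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    return CohortTable(make_cohort_df(30, rng))


@pytest.fixture(scope="session")
def default_cohort():
    """A seeded default synthetic cohort (with missingness), shared per session."""
    table, truths = generate_cohort(GeneratorConfig(seed=7))
    return table, truths


@pytest.fixture(scope="session")
def imputed_cohort(default_cohort):
    table, truths = default_cohort
    return io_cohort.preprocess(table, k=10), truths
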