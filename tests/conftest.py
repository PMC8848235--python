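"""Shared fixtures: synthetic study data at desk scale.

The expensive artifacts (the calibrated 780-day study table, its design
matrix, and the rolling LASSO/LSTM forecasts) are session-scoped so the
protocol, metric and inventory tests can share one computation.
"""

import numpy as np
import pandas as pd
import pytest

from bloodstock.features import build_design_matrix
from bloodstock.forecasting import (
    LassoConfig,
    lasso_factory,
    rolling_origin_forecast,
)
from bloodstock.synthetic import GeneratorConfig, generate_dataset

STUDY_SEED = 1
STUDY_N_DAYS = 780


@pytest.fixture(scope="session")
def study_data() -> pd.DataFrame:
    """Calibrated synthetic study table: 500 training + 280 evaluation days."""
    return generate_dataset(GeneratorConfig(n_days=STUDY_N_DAYS, seed=STUDY_SEED))


@pytest.fixture(scope="session")
def study_matrix(study_data) -> pd.DataFrame:
    return build_design_matrix(study_data)


@pytest.fixture(scope="session")
def lasso_models_and_forecasts(study_matrix):
    """Rolling-origin LASSO forecasts plus the per-iteration y2 fits."""
    models = []
    base = lasso_factory(LassoConfig())

    def recording(train, target):
        m = base(train, target)
        if target == "y2":
            models.append(m)
        return m

    forecasts = rolling_origin_forecast(recording, study_matrix, 500, 28, "lasso")
    return models, forecasts


@pytest.fixture(scope="session")
def lasso_forecasts(lasso_models_and_forecasts):
    return lasso_models_and_forecasts[1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_daily_table(demand, start="2015-01-05", **features) -> pd.DataFrame:
    """Tiny daily table helper for unit tests."""
    demand = np.asarray(demand)
    out = pd.DataFrame(
        {"date": pd.date_range(start, periods=len(demand), freq="D"),
         "demand": demand}
    )
    for name, col in features.items():
        out[name] = np.asarray(col)
    return out
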