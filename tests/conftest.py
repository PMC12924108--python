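import numpy as np
import pandas as pd
import pytest

import windlag as w
from windlag.model import CaseCrossoverModel, ModelConfig


@pytest.fixture(scope="session")
def small_panel():
    """A modest synthetic study reused across model tests."""
    cfg = w.GeneratorConfig(n_counties=10, n_states=2, year_range=(2014, 2019), seed=3)
    return w.generate_panel(cfg)


@pytest.fixture(scope="session")
def small_inputs(small_panel):
    return w.PanelInputs.from_synthetic(small_panel)


@pytest.fixture(scope="session")
def small_fit(small_inputs):
    model = CaseCrossoverModel.from_inputs(small_inputs, config=ModelConfig(seed=1))
    return model.fit()


@pytest.fixture()
def one_stratum_frame():
    """One county-month stratum: 3 member years, counts 2/5/3, one lag."""
    return pd.DataFrame(
        {
            "county_id": ["a"] * 3,
            "month_index": [8, 20, 32],
            "deaths": [2, 5, 3],
            "lag_0": [0.0, 1.0, 0.0],
            "lag_complete": [True] * 3,
            "population": [1000.0] * 3,
        }
    )


@pytest.fixture(scope="session")
def no_adjust_config():
    """Trend/temperature disabled, flat priors, exact conditional Poisson."""
    return ModelConfig(
        lag=0,
        use_trend=False,
        use_temperature=False,
        overdispersion="none",
        beta_prior_sd=np.inf,
        inference="map_laplace",
        draws=500,
        seed=0,
    )
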