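import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aircco import design, synthetic_data

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def year_config():
    """One-year, 6-tract study with a known NOx effect."""
    return synthetic_data.SimConfig(
        n_tracts=6,
        start_date=dt.date(2005, 1, 1),
        end_date=dt.date(2005, 12, 31),
        true_betas={"NOx": 0.01},
        target_daily_visits=3.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def year_exposures(year_config):
    return synthetic_data.generate_exposures(year_config)


@pytest.fixture(scope="session")
def year_visits(year_config, year_exposures):
    return synthetic_data.generate_visits(year_exposures, year_config)


@pytest.fixture(scope="session")
def year_rows(year_visits, year_exposures):
    rng = np.random.default_rng(7)
    rows, log = design.build_rows(year_visits, year_exposures, rng)
    return rows
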