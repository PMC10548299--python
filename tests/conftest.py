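import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import opometrics as om
from opometrics.area_profiles import county_quintiles

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_counties() -> pd.DataFrame:
    """Six counties, three OPOs, ADI spanning all five national quintiles."""
    return pd.DataFrame(
        {
            "county_id": ["a", "b", "c", "d", "e", "f"],
            "population": [1000, 2000, 3000, 4000, 5000, 6000],
            "adi": [10.0, 20.0, 30.0, 40.0, 50.0, 60.0],
            "opo": ["OPO1", "OPO1", "OPO2", "OPO2", "OPO3", "OPO3"],
        }
    )


@pytest.fixture(scope="session")
def tiny_crosswalk(tiny_counties) -> pd.DataFrame:
    return om.synthetic_cohort.make_crosswalk(tiny_counties, [2018, 2019])


@pytest.fixture(scope="session")
def small_config() -> om.ScenarioConfig:
    """A small but non-degenerate cohort used by integration-style tests."""
    return om.ScenarioConfig(
        n_counties=40,
        n_opos=10,
        mean_population=8000,
        donation_propensity=0.15,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return om.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_quintiles(small_cohort) -> pd.Series:
    return county_quintiles(small_cohort.counties.set_index("county_id")["adi"])


@pytest.fixture(scope="session")
def small_rates(small_config, small_cohort, small_quintiles) -> pd.DataFrame:
    return om.compute_all_measures(
        small_cohort.deaths,
        small_cohort.donors,
        small_cohort.crosswalk,
        small_quintiles,
        years=small_config.all_years,
    )
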