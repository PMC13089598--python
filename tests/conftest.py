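import numpy as np
import pandas as pd
import pytest

import droughtlegacy as dl


@pytest.fixture(scope="session")
def default_config():
    return dl.ScenarioConfig(seed=11)


@pytest.fixture(scope="session")
def default_scenario(default_config):
    drivers = dl.generate_drivers(default_config)
    fluxes = dl.generate_fluxes(drivers, default_config)
    return default_config, drivers, fluxes


@pytest.fixture(scope="session")
def small_config():
    """10-year record, drought in year 8, 2 post-drought years: fast fits."""
    return dl.ScenarioConfig(start_year=2003, end_year=2012, drought_year=2009,
                             post_drought_years=(2010, 2011), seed=5)


@pytest.fixture(scope="session")
def small_scenario(small_config):
    drivers = dl.generate_drivers(small_config)
    fluxes = dl.generate_fluxes(drivers, small_config)
    return small_config, drivers, fluxes


@pytest.fixture(scope="session")
def small_model_config(small_config):
    return dl.LegacyModelConfig(post_drought_years=small_config.post_drought_years,
                                n_trees=30, seed=3, target_name="GPP")


def daily_frame(values, start="2003-01-01"):
    """Daily series frame from an array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="D")
    return pd.DataFrame({"date": dates, "value": values})


def grid_365(values, start_year=2003):
    """Frame on the package's 365-day calendar (leap days skipped)."""
    values = np.asarray(values, dtype=float)
    n_years = int(np.ceil(len(values) / 365))
    cal = dl.year_days(start_year, start_year + n_years - 1).iloc[:len(values)]
    return pd.DataFrame({"date": cal["date"].to_numpy(), "value": values})
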