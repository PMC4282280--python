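import numpy as np
import pandas as pd
import pytest

from herdvuln import (
    CategoryConfig,
    CategorySpec,
    IndicatorTable,
    SyntheticConfig,
    extreme_nations_fixture,
    extreme_nations_indices,
    generate_nations,
)
from herdvuln.config import CLIMATE_MEMBERS


@pytest.fixture(scope="session")
def table2():
    """Published ranks and scores of the 30 extreme nations."""
    return extreme_nations_fixture()


@pytest.fixture(scope="session")
def table2_indices():
    """The 30 published (S, E, AC) triples, ready for the model stage."""
    return extreme_nations_indices()


@pytest.fixture(scope="session")
def minimal_config():
    """One generically named indicator per category plus the climate triple."""
    cats = [
        CategorySpec(name="self_sufficiency", code="ss", members=["ss_0"]),
        CategorySpec(name="food_insecurity", code="fs", members=["fs_0"]),
        CategorySpec(name="nutritional_contribution", code="nc", members=["nc_0"]),
        CategorySpec(name="climate", code="cc", members=list(CLIMATE_MEMBERS),
                     rule="composite-climate"),
        CategorySpec(name="population_growth", code="pg", members=["pg_0"]),
        CategorySpec(name="health", code="he", members=["he_0"]),
        CategorySpec(name="economy", code="ec", members=["ec_0"]),
        CategorySpec(name="governance", code="gv", members=["gv_0"]),
    ]
    return CategoryConfig(categories=cats)


@pytest.fixture
def five_nation_table(minimal_config):
    """Hand-built five-nation table with eight indicator columns."""
    rng = np.random.default_rng(42)
    n = 5
    data = pd.DataFrame({
        "nation_id": ["AAA", "BBB", "CCC", "DDD", "EEE"],
        "name": [f"Nation {i}" for i in range(n)],
        "region": ["South Asia", "Sub-Saharan Africa", "North America",
                   "Europe and Central Asia", "East Asia and Pacific"],
        "income_group": ["low", "low", "high", "high", "lower middle"],
        "developed_status": ["least developed", "developing", "developed",
                             "developed", "developing"],
        "food_deficit": [True, True, False, False, True],
        "population": [5_000_000, 12_000_000, 300_000_000, 80_000_000,
                       60_000_000],
        "ss_0": [0.9, 0.8, 0.3, 0.4, 0.6],
        "fs_0": [40.0, 35.0, 2.0, 3.0, 15.0],
        "nc_0": [30.0, 20.0, 10.0, 12.0, 25.0],
        "delta_t": [2.5, 3.0, 1.5, 1.2, 2.0],
        "delta_p": [-120.0, 80.0, 40.0, -30.0, 100.0],
        "extreme_weather_w": [25.0, 40.0, 5.0, 2.0, 30.0],
        "pg_0": [120.0, 90.0, 20.0, -5.0, 40.0],
        "he_0": [50.0, 55.0, 79.0, 81.0, 70.0],
        "ec_0": rng.lognormal(24, 1, n),
        "gv_0": [-1.5, -1.0, 1.5, 1.8, 0.0],
    })
    return IndicatorTable(data, minimal_config)


@pytest.fixture(scope="session")
def synth_cohort():
    """Default-condition synthetic cohort of 148 nations with latent truth."""
    return generate_nations(SyntheticConfig(n_nations=148, seed=11))
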