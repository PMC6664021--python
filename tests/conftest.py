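import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import uavpheno as up
from uavpheno.indices import add_vi_columns
from uavpheno.pipeline import segment_raster
from uavpheno.scenarios import ts1, ts2, ts3

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

#: one seed for the shared full-scale fixtures
SEED = 11


@pytest.fixture(scope="session")
def design():
    """Full-scale trial: 66 accessions x 3 blocks x 78 positions."""
    return up.generate_trial_design(66, 3, 78, seed=SEED)


@pytest.fixture(scope="session")
def phenotypes(design):
    return up.generate_phenotypes(design, seed=SEED)


@pytest.fixture(scope="session")
def phenology(design):
    return up.generate_phenology(design, seed=SEED)


@pytest.fixture(scope="session")
def plot_table(design, phenotypes, phenology):
    """Seven-date rendered + segmented + indexed plot table (the expensive bit)."""
    tables = []
    for date in up.FLIGHT_DATES:
        raster = up.render_orthomosaic(design, phenotypes, phenology, date, seed=SEED)
        tables.append(segment_raster(raster, design))
    import pandas as pd

    return add_vi_columns(pd.concat(tables, ignore_index=True))


@pytest.fixture(scope="session")
def scenario_tables(plot_table, phenology):
    out = {f"TS1@{d}": ts1(plot_table, d) for d in up.FLIGHT_DATES}
    out["TS2"] = ts2(plot_table, phenology)
    out["TS3"] = ts3(plot_table)
    return out


@pytest.fixture(scope="session")
def small_trial():
    """Cheap trial for unit tests: 8 accessions x 2 blocks x 10 positions."""
    design = up.generate_trial_design(8, 2, 10, seed=3)
    phenotypes = up.generate_phenotypes(design, seed=3)
    phenology = up.generate_phenology(design, seed=3)
    return design, phenotypes, phenology
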