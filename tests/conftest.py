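"""Shared fixtures: grids, parameter sets, and the long column runs.

The multi-decade runs are session-scoped because several tests read
different diagnostics off the same simulation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mpsink import RunConfig, default_grid, fixture

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid19():
    return default_grid()


@pytest.fixture(scope="session")
def test_med():
    return fixture("test_med")


@pytest.fixture(scope="session")
def tropical_run():
    """Warm productive column (28 degC), TestMed parameters, 1950-2020."""
    cfg = RunConfig(surface_C=28.0, end_year=2020, spinup_years=20)
    return cfg.build_simulation().run(1950, 2020, spinup_years=20)


@pytest.fixture(scope="session")
def midlat_run():
    """Mid-latitude column (12 degC), TestMed parameters, 1950-2020."""
    cfg = RunConfig(surface_C=12.0, end_year=2020, spinup_years=20)
    return cfg.build_simulation().run(1950, 2020, spinup_years=20)


def annual_uptake_export_ratio(result, year: int) -> float:
    """Gross biological MP uptake above 130 m over MP export at 130 m."""
    row = result.scalars.set_index("year").loc[year]
    uptake = row["a_upt_above"] + row["p_upt_above"]
    export = row["mpa_flux_130"] + row["mpz_flux_130"]
    return uptake / export


@pytest.fixture(scope="session")
def short_run():
    """A cheap 6-year run for structural and I/O tests."""
    cfg = RunConfig(end_year=1956, spinup_years=5)
    return cfg.build_simulation().run(1950, 1956, spinup_years=5)
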