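import numpy as np
import pytest

from ecosink.forcing import gen_forcing
from ecosink.grid import gen_grid
from ecosink.params import load_default_params


@pytest.fixture(scope="session")
def params():
    return load_default_params()


@pytest.fixture(scope="session")
def small_grid():
    """3x3 grid spanning the vegetated latitudes."""
    return gen_grid(3, 3, (-50.0, 70.0), seed=7)


@pytest.fixture(scope="session")
def small_forcing(small_grid):
    """Noisy forcing, 1971-2016, observed CO2/N-deposition endpoints."""
    grid, static = small_grid
    return gen_forcing(grid, static, (1971, 2016), seed=7,
                       met_trend={"tmax": 0.25, "tmin": 0.25})


@pytest.fixture(scope="session")
def tiny_equilibrium(params):
    """2x2 world spun to equilibrium: shared by the pool-property and
    scenario tests (the spin-up itself is exercised in its own tests)."""
    from ecosink import spinup as sp

    grid, static = gen_grid(2, 2, (-30.0, 60.0), seed=11)
    forcing = gen_forcing(grid, static, (1951, 2016), seed=11,
                          co2_endpoints=(311.0, 404.2),
                          ndep_endpoints_tg=(25.0, 58.9),
                          met_trend={"tmax": 0.25, "tmin": 0.25})
    state, report = sp.spinup_1901(
        forcing, params, start_year=1951, climate_window=(1951, 1955),
        lai_window=(1982, 1986), probe_years=3, settle_years=3,
        outer_iterations=2, seed=5)
    return forcing, state, report
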