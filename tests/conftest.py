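import numpy as np
import pandas as pd
import pytest

import fieldfit as ff
from fieldfit.weather import resample_weather


@pytest.fixture(scope="session")
def season_weather():
    """Synthetic Tsukuba-like record covering the 2008 benchmark season."""
    return ff.benchmark_weather(years=(2008,), step=600, seed=11)


@pytest.fixture(scope="session")
def schedule_4h():
    return ff.sampling_design("4h", 2008)


@pytest.fixture(scope="session")
def small_weather():
    """Three days of 10-min weather, cheap enough for brute-force oracles."""
    return ff.synth_weather("2008-06-01", "2008-06-04", step=600, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_design(schedule_4h, season_weather):
    """A concrete 180 x 9 design matrix with a temperature response column."""
    ws = resample_weather(season_weather, 600)
    rp = ff.ResponseParams(
        factor="temperature", period_p=6.0, threshold_theta=26.0,
        gamma_f=-4.0, gamma_g=10.0, theta_g=-2.0, psi=0.0, sign_rho=1,
    )
    return ff.build_design_matrix(
        schedule_4h.times, schedule_4h.ages, schedule_4h.genotypes, ws, rp
    )
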