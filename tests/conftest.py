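import numpy as np
import pandas as pd
import pytest

from emsafit import ModelParams, Scenario, TitrationSeries, simulate_series


@pytest.fixture
def wt_params():
    """Cooperative reference parameters used across tests."""
    return ModelParams(kd=40.0, C=5.0, f=0.85)


@pytest.fixture
def wt_scenario(wt_params):
    return Scenario("wt_sps", wt_params, noise_sd=0.02, seed=11)


@pytest.fixture
def wt_series(wt_scenario):
    return simulate_series(wt_scenario)


@pytest.fixture
def noiseless_series(wt_params):
    scen = Scenario("noiseless", wt_params, noise_sd=0.0, seed=0)
    return simulate_series(scen)


def make_series(condition="cond", conc=(2.5, 10.0, 40.0), reps=1, bands=None):
    """Small hand-built series; bands defaults to a plausible monotone shift."""
    rows = []
    for i, c in enumerate(conc):
        for r in range(1, reps + 1):
            if bands is None:
                b = (100.0 - 10.0 * i, 20.0 + 5.0 * i, 5.0 * i + 1.0)
            else:
                b = bands[i]
            rows.append((c, r, *b))
    lanes = pd.DataFrame(
        rows, columns=["conc_nM", "replicate", "band0", "band1", "band2"]
    )
    return TitrationSeries(condition, lanes)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
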