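import numpy as np
import pytest
from hypothesis import settings

import rodcascade as rc

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def nob():
    return rc.fixture_parameters("NOB")


@pytest.fixture(scope="session")
def drug():
    return rc.fixture_parameters("NOB_drug")


@pytest.fixture(scope="session")
def wild():
    return rc.fixture_parameters("wild")


@pytest.fixture(scope="session")
def fit_grid():
    """1 kHz sampling over the 0.28 s a-wave fit horizon."""
    return rc.SimulationGrid(0.0, 0.28, 1e-3, 5e-5)


@pytest.fixture(scope="session")
def fit_stimulus():
    """Light held on through the fit horizon."""
    return rc.Stimulus(0.0, 0.29)


@pytest.fixture(scope="session")
def nob_fit_trace(nob, fit_grid, fit_stimulus):
    """Noiseless NOB trace on the fit horizon, negative-going polarity."""
    trace, truth = rc.generate_trace("NOB", stimulus=fit_stimulus, grid=fit_grid)
    return trace, truth
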