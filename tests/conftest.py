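import numpy as np
import pytest

import flavokin as fk


@pytest.fixture(scope="session")
def visible_grid():
    """Wavelength grid covering the flavin visible bands (nm)."""
    return np.arange(360.0, 551.0, 2.5)


@pytest.fixture(scope="session")
def nadh_series():
    """Synthetic 1:1 NADH-reduction acquisition (rates 78, 8.9 s^-1, 2% noise)."""
    return fk.simulate_stopped_flow(fk.scenario_preset("nadh_2step", seed=7))


@pytest.fixture(scope="session")
def nadh_concentrations():
    """1:1 to 1:14 coenzyme ladder over 7.5 µM enzyme (µM)."""
    return np.array([7.5, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0, 105.0])
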