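import numpy as np
import pytest

import phenoshift as ps


@pytest.fixture(scope="session")
def climate_temps():
    """A 130-year synthetic daily temperature series shared across tests."""
    return ps.simulate_temperature(ps.ClimateSpec(seed=11), 1800, 130)


@pytest.fixture(scope="session")
def toy_temps():
    """A short series for brute-force oracle comparisons."""
    return ps.simulate_temperature(ps.ClimateSpec(seed=5), 1900, 21)


@pytest.fixture(scope="session")
def uniforc_truth():
    return ps.UniForcParams(t1=20, b_f=-0.3, c_f=10.0, F_star=30.0)


@pytest.fixture(scope="session")
def unichill_truth():
    from phenoshift.calendar import SEP1_PREV_OFFSET

    return ps.UniChillParams(
        t0=SEP1_PREV_OFFSET, a_c=0.0, b_c=1.2, c_c=4.0, C_star=45.0,
        b_f=-0.5, c_f=9.0, F_star=18.0,
    )


@pytest.fixture(scope="session")
def constant_rate_setup():
    """Constant 10 degC series giving forcing rate exactly 0.5/day at b_f=-1, c_f=10."""
    offsets = np.arange(-10, 251)
    X = np.full((1, len(offsets)), 10.0)
    return X, offsets
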