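import numpy as np
import pytest

import oxymat as om


@pytest.fixture(scope="session")
def kinetics():
    return om.KineticParameters()


@pytest.fixture(scope="session")
def transport_params():
    return om.TransportParameters()


@pytest.fixture(scope="session")
def small_grid():
    """10 mm domain at 0.284 mm spacing: fast converge-mode runs."""
    return om.Grid1D.from_depth(10.0, 0.284)


@pytest.fixture(scope="session")
def deep_grid():
    """30 mm domain at 0.5 mm spacing: spans oxic and anoxic regimes."""
    return om.Grid1D.from_depth(30.0, 0.5)


@pytest.fixture(scope="session")
def oxic_result(kinetics, transport_params, small_grid):
    """Converged oxic-day steady state on the small grid (shared, read-only)."""
    return om.simulate_scenario(kinetics, transport_params, small_grid,
                                "oxic_day", dt=20.0)


@pytest.fixture(scope="session")
def linear_o2_profile():
    z = np.linspace(0.0, 5.0, 21)
    return om.DepthProfile(z, 230.0 - 20.0 * z, kind="o2_concentration")
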