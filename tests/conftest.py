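import numpy as np
import pytest

import rescomp as rc


@pytest.fixture
def symmetric_three() -> rc.Community:
    """Equal-budget community with the supply point inside the hull."""
    R = np.array([[0.6, 0.2, 0.2], [0.2, 0.6, 0.2], [0.2, 0.2, 0.6]])
    return rc.Community(R, np.full(3, 1 / 3), 1.0)


@pytest.fixture
def two_specialists() -> rc.Community:
    return rc.Community(np.eye(2), np.array([0.5, 0.5]), 1.0)


def ode_survivors(community: rc.Community, **kwargs):
    """Survivor set via the dynamical route (independent of geometry)."""
    ss = rc.steady_state(community, **kwargs)
    assert ss.converged, "ODE steady state did not converge"
    return ss
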