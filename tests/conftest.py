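import numpy as np
import pytest

import growsim as gs


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def curved_state(rng):
    """Smoothly curved 3D organ state with a clamped base."""
    n = 120
    s = np.arange(n) * 0.01
    kappa1 = 0.8 * np.sin(2 * np.pi * s)
    kappa2 = 0.5 * np.cos(3 * np.pi * s) - 0.5
    kappa1[0] = kappa2[0] = 0.0
    return gs.OrganState(
        kappa1=kappa1,
        kappa2=kappa2,
        ds=0.01,
        base_frame=np.eye(3),
        base_position=np.zeros(3),
        growth_zone_length=1.0,
        radius=0.1,
    )
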