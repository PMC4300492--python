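import numpy as np
import pytest

from sizecontrol import CycleTimeFunction, GrowthParams


@pytest.fixture
def gradual_f():
    """Cycle-time law bracketing log(2)/lam for lam=0.2: T in [2, 4] h."""
    return CycleTimeFunction(T_min=2.0, T_max=4.0, v_half=0.0, width=1.0)


@pytest.fixture
def homeostatic_params():
    return GrowthParams(lam=0.2, n=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
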