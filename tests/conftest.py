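import math

import numpy as np
import pytest

from cellcap import DivisionRule, GrowthLaw

ALPHA = 1.0 / 48.0


@pytest.fixture(scope="session")
def builtin_laws():
    """One representative instance per built-in growth-law kind."""
    return {
        "exponential": GrowthLaw.exponential(ALPHA),
        "linear": GrowthLaw.linear(1.0),
        "saturating": GrowthLaw.saturating(ALPHA, 25.0),
        "power_saturating": GrowthLaw.power_saturating(ALPHA, 20.0, 3.0),
        "reciprocal": GrowthLaw.reciprocal(ALPHA, 30.0),
    }


@pytest.fixture(scope="session")
def adder_rule():
    """The canonical adder scenario: a=1, V̄=30 μm, 20 h cycle floor."""
    return DivisionRule(a=1.0, vbar=30.0, tmin=20.0)


@pytest.fixture(scope="session")
def doubling_time():
    """Cycle duration at the adder fixed point under exponential growth."""
    return 48.0 * math.log(2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
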