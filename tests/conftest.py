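import numpy as np
import pytest

from roppol import ModelConstants, Rates, solve_reference


@pytest.fixture(scope="session")
def ref():
    """Reference bell shape at the working exponent alpha = 1.2, c = 15."""
    return solve_reference(alpha=1.2, c=15.0)


@pytest.fixture(scope="session")
def consts():
    return ModelConstants()


@pytest.fixture(scope="session")
def wt_rates():
    """Wild-type-like feedback rates used throughout the study designs."""
    return Rates(knf=0.2, kpf=0.3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
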