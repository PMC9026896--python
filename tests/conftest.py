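import numpy as np
import pytest

import metkit as mk


@pytest.fixture
def untreated_fit() -> mk.GrowthFit:
    """The calibrated untreated power law (A0 = 0.0019 mm², B = 4.1)."""
    return mk.GrowthFit(family="power", amplitude=0.0019, exponent=4.1)


@pytest.fixture
def treated_fit() -> mk.GrowthFit:
    """The calibrated treated power law (A0 = 0.0087 mm², B = 3.0)."""
    return mk.GrowthFit(family="power", amplitude=0.0087, exponent=3.0)


@pytest.fixture
def exponential_fit() -> mk.GrowthFit:
    """The calibrated exponential law (A0 = 0.05 mm², k = 0.45 /day)."""
    return mk.GrowthFit(family="exponential", amplitude=0.05, exponent=0.45)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
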