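import numpy as np
import pytest

from nzest import default_grid, make_test_distribution


@pytest.fixture(scope="session")
def grid9():
    return default_grid(9)


@pytest.fixture(scope="session")
def grid6():
    return default_grid(6)


@pytest.fixture(scope="session")
def truths():
    """All 9-bin benchmark distributions by name."""
    names = ("uniform", "dirac", "normal_narrow", "normal_wide", "bimodal", "irregular")
    return {name: make_test_distribution(name) for name in names}


@pytest.fixture()
def rng():
    return np.random.default_rng(20180813)
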