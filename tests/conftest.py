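import itertools

import pytest

from sfdi_layers import (
    FluenceModelChoice,
    OpticalProperties,
    make_phantom_suite,
    default_frequency_grid,
)

ALL_MODELS = list(FluenceModelChoice)

#: parameter box on which the fluence models are certified
GRID_MU_A = (0.01, 0.05, 0.1)
GRID_MU_S = (0.5, 1.0, 2.0, 5.0)
GRID_G = (0.7, 0.8, 0.9)
GRID_FX = (0.0, 0.1, 0.3, 0.5)


def certified_grid_points():
    for mu_a, mu_s, g, fx in itertools.product(GRID_MU_A, GRID_MU_S, GRID_G, GRID_FX):
        yield OpticalProperties(mu_a=mu_a, mu_s_prime=mu_s, g=g, n=1.4), fx


@pytest.fixture(scope="session")
def fig2_props():
    """Reference homogeneous medium used in the fluence-profile comparisons."""
    return OpticalProperties(mu_a=0.05, mu_s_prime=5.0, g=0.8, n=1.4)


@pytest.fixture(scope="session")
def grid11():
    return default_frequency_grid()


@pytest.fixture(scope="session")
def suite():
    return make_phantom_suite()
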