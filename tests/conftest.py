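import numpy as np
import pytest

from grnfvm import (
    DegradationSpec,
    GRNModel,
    RegulationSpec,
    TruncatedGrid,
    assemble_generator,
)


def make_constant_model(n=1, km=1.0, b=1.0, gamma=1.0, L=3.0):
    """Unregulated model with constant rates (c = 1), for structural tests."""
    if np.isscalar(km):
        km = (km,) * n
    if np.isscalar(b):
        b = (b,) * n
    if np.isscalar(L):
        L = (L,) * n
    return GRNModel(
        n=n,
        km=tuple(km),
        burst=tuple(b),
        regulation=tuple(RegulationSpec("constant") for _ in range(n)),
        degradation=tuple(DegradationSpec("constant", rate=gamma) for _ in range(n)),
        domain=tuple(L),
    )


@pytest.fixture(scope="session")
def toy_grid():
    """Three unit cells on [0, 3)."""
    return TruncatedGrid([3], [3.0])


@pytest.fixture(scope="session")
def toy_model():
    """km = b = gamma = 1, unregulated: every coefficient is hand-checkable."""
    return make_constant_model(n=1, km=1.0, b=1.0, gamma=1.0, L=3.0)


@pytest.fixture(scope="session")
def toy_generator(toy_grid, toy_model):
    return assemble_generator(toy_grid, toy_model)


# Hand-assembled 3x3 generator: burst coefficients from the exponential
# antiderivative (b_self = -2 e^{-1/2}, beta_bar = e^{-1/2} - e^{-3/2},
# tails e^{-1/2}, e^{-3/2}) plus degradation face speeds 1 and 2.
TOY_MATRIX = np.array(
    [
        [-0.60653, 1.0, 0.0],
        [0.38340, -1.60653, 2.0],
        [0.22313, 0.60653, -2.0],
    ]
)

# Equilibrium of the toy system solved by hand from the 3x3 linear system
# with the unit-mass constraint.
TOY_EQUILIBRIUM = np.array([0.5258, 0.3189, 0.1554])
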