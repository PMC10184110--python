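import numpy as np
import pytest

from ctrlbranch import (
    BinomialThinningKernel,
    EmigrationKernel,
    EnvironmentLaw,
    EnvironmentState,
    IdentityKernel,
    ImmigrationKernel,
    get_scenario,
)


@pytest.fixture
def theta1():
    """Critical reference state: offspring {0:.25, 1:.25, 2:.5}, alpha 0.8, identity."""
    return EnvironmentState("theta1", np.array([0.25, 0.25, 0.5]), 0.8, IdentityKernel())


@pytest.fixture
def theta1_em():
    """theta1 offspring with random emigration (one leaves w.p. 1/2)."""
    return EnvironmentState("theta1_em", np.array([0.25, 0.25, 0.5]), 0.8, EmigrationKernel([0.5, 0.5]))


@pytest.fixture
def theta3():
    """Supercritical state: thinned pgf 0.36 + 0.16 s + 0.48 s^2."""
    return EnvironmentState("theta3", np.array([0.2, 0.2, 0.6]), 0.8, IdentityKernel())


@pytest.fixture
def single_state_law():
    def make(state):
        return EnvironmentLaw([state], np.array([1.0]))

    return make


@pytest.fixture(params=["S1_critical", "S2_subcritical", "S3_supercritical_gw", "S4_two_state", "S5_emigration", "S6_reduction_alpha1"])
def scenario(request):
    return get_scenario(request.param)


@pytest.fixture
def all_kernels():
    return [
        IdentityKernel(),
        BinomialThinningKernel(0.9),
        EmigrationKernel([0.5, 0.5]),
        EmigrationKernel([0.2, 0.5, 0.3]),
        ImmigrationKernel([0.7, 0.2, 0.1]),
    ]
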