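import numpy as np
import pytest

from ewsbench.model import (
    ModelParameters,
    default_4d_parameters,
    default_4d_sweep,
    sweep_bifurcation_parameter,
)


@pytest.fixture(scope="session")
def params_4d():
    return default_4d_parameters(reactive=False)


@pytest.fixture(scope="session")
def params_4d_reactive():
    return default_4d_parameters(reactive=True)


@pytest.fixture(scope="session")
def sweep_4d():
    """Calibrated non-reactive 4D sweep, 50 steps."""
    params, r0, r1 = default_4d_sweep(reactive=False)
    return sweep_bifurcation_parameter(params, r0, r1, 50)


@pytest.fixture(scope="session")
def sweep_4d_reactive():
    params, r0, r1 = default_4d_sweep(reactive=True)
    return sweep_bifurcation_parameter(params, r0, r1, 50)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def single_species_params(r=0.3, c=0.3, sigma=0.02):
    """Two decoupled 1-species guilds (no mutualism): logistic dynamics."""
    return ModelParameters(
        n_pollinators=1,
        n_plants=1,
        r_A=[r],
        r_P=[r],
        gamma_A=[[0.0]],
        gamma_P=[[0.0]],
        c_A=[[c]],
        c_P=[[c]],
        h_A=[0.5],
        h_P=[0.5],
        sigma_A=[sigma],
        sigma_P=[sigma],
    )
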