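import numpy as np
import pytest
from hypothesis import settings

from sigmabnn import (
    KineticParameters,
    NetworkSpec,
    NodeSpec,
    SignedWeight,
    load_preset,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def fig4e():
    return load_preset("fig4e_bandstop")


@pytest.fixture
def fig4h():
    return load_preset("fig4h_bandpass")


@pytest.fixture
def single_perceptron():
    """Isolated perceptron, fast sequestration (r = 0.01), c_tot = 0.2 uM."""
    return load_preset("fig2_resources", gamma1=1000.0, c_tot=0.2)


@pytest.fixture
def single_sigma_only():
    """One node producing only sigma (no antisigma source), for closed forms."""
    node = NodeSpec(node_id="n1", layer=1, input_weights={"x1": SignedWeight(1.0, +1)})
    return NetworkSpec(
        nodes=(node,),
        c_tot=0.2,
        kinetics=KineticParameters(gamma1=1000.0, gamma2=10.0, delta=1.0),
    )


def grid_points(resolution: int, x_max: float = 1.0) -> np.ndarray:
    axis = np.linspace(0.0, x_max, resolution)
    return axis
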