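import numpy as np
import pytest

from fogsim.cpg import CPGNetwork, generate_teach_signals, train_cpg
from fogsim.locomotion import GaitGeometry, StrideModel


@pytest.fixture(scope="session")
def trained_network() -> CPGNetwork:
    """Default three-pool network trained to convergence on the default
    teach signals (deterministic)."""
    net = CPGNetwork()
    result = train_cpg(net, generate_teach_signals())
    assert result.converged
    return net


@pytest.fixture(scope="session")
def stride_model(trained_network) -> StrideModel:
    return StrideModel(trained_network, GaitGeometry(mode="stride"))


@pytest.fixture(scope="session")
def step_model(trained_network) -> StrideModel:
    return StrideModel(trained_network, GaitGeometry(mode="step"))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
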