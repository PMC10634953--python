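import numpy as np
import pytest

from prebotc.biophysics import IonEnvironment, NeuronParameters
from prebotc.engine import SimulationConfig
from prebotc.network import NetworkSpec, build_network


@pytest.fixture(scope="session")
def env():
    return IonEnvironment()


@pytest.fixture(scope="session")
def canonical():
    """The canonical intrinsic burster: g_NaP = 3.33 nS, g_Leak = 3.5 nS."""
    return NeuronParameters()


@pytest.fixture(scope="session")
def tiny_network(env):
    """Seeded N = 10 realization for fast coupled-network tests."""
    return build_network(NetworkSpec(N=10, seed=7), env, seed=7)


@pytest.fixture
def short_cfg():
    return SimulationConfig(duration=2000.0, transient=0.0)
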