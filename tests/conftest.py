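import numpy as np
import pytest

from symcell import SimConfig, build_network_1, build_network_2, run_ncell
from symcell.analysis import division_rate


@pytest.fixture(scope="session")
def net1():
    return build_network_1()


@pytest.fixture(scope="session")
def net2():
    return build_network_2()


@pytest.fixture(scope="session")
def ncell_run_net1():
    """One full-scale N-cell run of the six-species cross-feeding network.

    Shared across the tests that need a differentiated population (the run
    is by far the most expensive piece of the suite). Parameters are the
    published worked-example set (C, V_med, D) = (0.15, 100, 1) at N = 100;
    the horizon is 1e4 time units, long enough for the population to fill
    the medium and split into the two cross-feeding types.
    """
    net = build_network_1()
    cfg = SimConfig(
        N=100, C=0.15, V_med=100.0, D=1.0, t_max=1e4, record_interval=20.0, seed=1
    )
    return net, cfg, run_ncell(net, cfg)


@pytest.fixture(scope="session")
def isolated_run_net1():
    """Matching isolated (N = 1) run with otherwise identical parameters."""
    net = build_network_1()
    cfg = SimConfig(
        N=1, C=0.15, V_med=100.0, D=1.0, t_max=1e4, record_interval=20.0, seed=1
    )
    return net, cfg, run_ncell(net, cfg)
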