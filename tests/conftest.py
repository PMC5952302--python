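"""Shared fixtures: reduced-scale experiment runs reused across the suite.

The reduced preset (N = 20 ring, 2 sites, 2/6/12/12 s periods) keeps every
structural feature of the full setup; running it once per protocol and
sharing the results keeps the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

import crstim
from crstim.engine import Simulator, initialize_network
from crstim.model import gate_steady_state
from crstim.params import ExperimentConfig, NetworkParams, Periods, StimParams


@pytest.fixture(scope="session")
def smoke_nostim():
    return crstim.run_experiment(crstim.smoke_config("no_stim", sample_id=1))


@pytest.fixture(scope="session")
def smoke_rvs():
    return crstim.run_experiment(crstim.smoke_config("RVS_CR", sample_id=1))


@pytest.fixture(scope="session")
def smoke_fixed():
    return crstim.run_experiment(crstim.smoke_config("fixed_CR", sample_id=1))


@pytest.fixture(scope="session")
def smoke_cmns():
    return crstim.run_experiment(crstim.smoke_config("CMNS", sample_id=1))


@pytest.fixture(scope="session")
def isolated_run():
    """A single uncoupled neuron at I = 11 uA/cm^2, integrated for 2 s."""
    net = NetworkParams.with_geometry(N=2, Ns=1)
    cfg = ExperimentConfig(
        net=net, stim=StimParams(Ns=1, stim_on_duration_s=128.0), periods=Periods()
    )
    state = initialize_network([7, 7], net)
    state.c[:] = 0.0
    state.I[:] = 11.0
    state.V[:] = -65.0
    m, h, n = gate_steady_state(-65.0)
    state.m[:], state.h[:], state.n[:] = m, h, n
    state.s[:] = 0.0
    state.t = 0.0
    sim = Simulator(cfg, state)
    sim.run(2000.0, stdp_enabled=False)
    return sim


@pytest.fixture
def tiny_config():
    """A very short (N = 10, 0.5/1/2/2 s) config for determinism-style tests."""
    net = NetworkParams.with_geometry(N=10, Ns=2)
    stim = StimParams(Ns=2, stim_on_duration_s=2.0)
    periods = Periods(init_s=0.5, stdp_only_s=1.0, stim_on_s=2.0, stim_off_s=2.0)
    return ExperimentConfig(
        protocol="RVS_CR", K=0.25, net=net, stim=stim, periods=periods
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
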