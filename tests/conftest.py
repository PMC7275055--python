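"""Shared fixtures: small synthetic datasets reused across test modules."""

from dataclasses import replace

import numpy as np
import pytest

import smfretkit as sk


@pytest.fixture(scope="session")
def default_dataset():
    """1000 equilibrium traces from the default three-state conditions."""
    cfg = replace(sk.preset("default"), seed=42)
    return sk.simulate_dataset(cfg, 1000)


@pytest.fixture(scope="session")
def reaction_dataset():
    """270 real-time reaction traces (full reaction mix injection)."""
    cfg = replace(sk.preset("thioester_reaction"), seed=7)
    return sk.simulate_dataset(cfg, 270)


@pytest.fixture()
def noise_free_config():
    return sk.SimulationConfig(
        noise_sigma=0.0,
        bleach_rate_donor=0.0,
        bleach_rate_acceptor=0.0,
        dynamic_fraction=0.0,
        n_frames=50,
    )


def constant_trace(e=0.5, n=100, total=1000.0, alpha=0.88, dt=0.1, molecule_id=0):
    """Noise-free trace at constant apparent efficiency ``e``."""
    i_d, i_a = sk.invert_efficiency(e, total, alpha)
    return sk.Trace(
        molecule_id=molecule_id,
        time=np.arange(n) * dt,
        donor=np.full(n, i_d),
        acceptor=np.full(n, i_a),
    )


@pytest.fixture()
def make_constant_trace():
    return constant_trace
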