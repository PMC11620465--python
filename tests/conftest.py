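"""Shared fixtures: desk-scale regime comparisons reused across tests.

The paired-condition fixtures simulate at a reduced protocol (30 s of
simulated time, 10 s transient, so 20 000 LFP samples) to keep the suite
fast; seeds are matched between ephaptic-on and -off members so the regime
is the only difference within a pair.
"""

import numpy as np
import pytest

import ephapsim as es

DESK_DURATION = 30.0


def condition_ks(n_seeds, seed_base=0, duration=DESK_DURATION, **kw):
    """K per seed for one condition at desk scale."""
    ks = []
    for i in range(n_seeds):
        cfg = es.SimulationConfig(duration=duration, seed=seed_base + i, **kw)
        lfp = es.run_network(cfg)
        ks.append(es.complexity_K(es.mse_curve(lfp.x)).K)
    return np.array(ks)


def paired_ks(n_seeds, **kw):
    """(K_on, K_off) arrays over matched seeds."""
    on = condition_ks(n_seeds, ephaptic_enabled=True, **kw)
    off = condition_ks(n_seeds, ephaptic_enabled=False, **kw)
    return on, off


@pytest.fixture(scope="session")
def headline_pair():
    """N=100, nb=4, rp=0.1, omega=5: the weak-synapse regime comparison."""
    return paired_ks(10, omega=5.0)


@pytest.fixture(scope="session")
def strong_synapse_pair():
    """Same topology at omega=30: the strong-synapse regime comparison."""
    return paired_ks(10, omega=30.0)


@pytest.fixture(scope="session")
def size_trend():
    """K at N=50 and N=200 for both regimes, 8 matched seeds each."""
    out = {}
    for n in (50, 200):
        out[n] = paired_ks(8, n_neurons=n)
    return out


@pytest.fixture(scope="session")
def neighborhood_trend():
    """K at nb=4 and nb=12 (N=200, omega=5) for both regimes, 8 seeds."""
    out = {}
    for nb in (4, 12):
        out[nb] = paired_ks(8, n_neurons=200, nb=nb)
    return out


@pytest.fixture(scope="session")
def default_run():
    """One full-length default-protocol realisation (60 s, M=50000)."""
    cfg = es.SimulationConfig(seed=1)
    return es.run_network(cfg, full_result=True)
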