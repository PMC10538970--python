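import numpy as np
import pytest

import phikinet as pk
from phikinet.fixtures import p0_grid, random_submechanism, table1_system
from phikinet.simulate import simulate_to_steady


@pytest.fixture(scope="session")
def table1():
    """The photoreversible reference system and its irradiation setup."""
    return table1_system()


@pytest.fixture(scope="session")
def table1_trace(table1):
    m, s = table1
    return pk.simulate(m, s, t_end=300.0, dt=0.1)


@pytest.fixture(scope="session")
def table1_fit(table1, table1_trace):
    m, _ = table1
    return pk.fit_species_traces(table1_trace, m, seed=1)


@pytest.fixture(scope="session")
def p0_runs(table1):
    """Calibration runs of the reference system over a 5-point flux grid."""
    m, _ = table1
    runs = []
    for setup in p0_grid():
        tr = simulate_to_steady(m, setup, dt=0.1, max_points=600)
        cf = pk.fit_species_traces(tr, m, seed=11)
        runs.append((setup, tr, cf))
    return runs


@pytest.fixture(scope="session")
def rate_battery():
    """Randomized sub-mechanisms with their traces and coupled fits."""
    rng = np.random.default_rng(2024)
    out = []
    for i in range(20):
        m, s = random_submechanism(rng)
        tr = simulate_to_steady(m, s)
        cf = pk.fit_species_traces(tr, m, seed=500 + i, fit_atot=False)
        out.append((m, s, tr, cf))
    return out
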