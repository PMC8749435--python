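"""Shared fixtures: expensive steady-state computations are session-scoped."""

import numpy as np
import pytest

from spo0relay.params import KineticParameters, WT, DELTA_KINC
from spo0relay.heterogeneity import HeterogeneityConfig, single_cell_population
from spo0relay import relay, growth_law


@pytest.fixture(scope="session")
def kinetics():
    return KineticParameters()


@pytest.fixture(scope="session")
def scan_rows(kinetics):
    """Spo0A~P fraction rows at low (0.03 uM) and high (3 uM) KinA over a
    KinC axis, for the reverse-transfer variant."""
    kinc_axis = np.array([0.0, 0.1, 0.3, 1.0, 3.0])
    frac, errors = relay.scan_kinase_plane(kinetics, [0.03, 3.0], kinc_axis)
    assert not errors
    return kinc_axis, frac


@pytest.fixture(scope="session")
def late_populations(kinetics):
    """WT and dkinC single-cell snapshots late in starvation (t = 6.5 h)."""
    config = HeterogeneityConfig(n_cells=300, seed=11)
    pops = {}
    for name, strain in (("WT", WT), ("dkinC", DELTA_KINC)):
        pops[name] = single_cell_population(6.5, strain, config, kinetics)
    return pops


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
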