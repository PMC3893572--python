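import numpy as np
import pytest

import lfpsim as L


@pytest.fixture(scope="session")
def passive():
    return L.CompartmentalizationParams()


@pytest.fixture()
def ball_and_stick_cell(passive):
    m = L.make_ball_and_stick(20.0, 500.0, 2.0, 11)
    return L.compartmentalize(m, passive)


@pytest.fixture()
def two_compartment_cell(passive):
    """Minimal dipole-capable cell: a short stick split in two."""
    m = L.make_stick(100.0, 2.0, 2)
    return L.compartmentalize(m, passive, nseg_override={"dend": 2})


@pytest.fixture()
def zigzag_morphology():
    """A single dendritic section whose 3D path zig-zags in the x–z plane."""
    xyz = np.array([
        [0.0, 0.0, 0.0],
        [30.0, 0.0, 40.0],
        [-20.0, 0.0, 90.0],
        [25.0, 0.0, 140.0],
        [0.0, 0.0, 200.0],
    ])
    diam = np.full(5, 2.0)
    types = np.full(5, 3, dtype=int)
    parents = np.arange(5) - 1
    m = L.Morphology3D(xyz, diam, types, parents, [("dend", np.arange(5))])
    m.validate()
    return m
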