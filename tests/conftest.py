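import numpy as np
import pytest

from megspect import synth, sourceest


@pytest.fixture(scope="session")
def geometry64():
    """Desk-type geometry shared by source-space tests: 64 ch, 250 vtx."""
    sensors, head = synth.make_geometry(
        n_channels=64, n_vertices=250, n_regions=68, seed=11
    )
    return sensors, head


@pytest.fixture(scope="session")
def leadfield64(geometry64):
    sensors, head = geometry64
    return sourceest.compute_lead_field(head, sensors)


@pytest.fixture(scope="session")
def inverse64(leadfield64):
    return sourceest.compute_inverse_operator(leadfield64)


@pytest.fixture(scope="session")
def tiny_geometry():
    """Minimal geometry for cheap end-to-end paths: 16 ch, 80 vtx, 8 regions."""
    sensors, head = synth.make_geometry(
        n_channels=16, n_vertices=80, n_regions=8, seed=5
    )
    return sensors, head


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
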