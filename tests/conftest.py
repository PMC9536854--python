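import numpy as np
import pytest

from scstim.dc_axon import compartment_potentials, find_activation_threshold, make_fiber
from scstim.stimulation import ElectrodePair, FieldModel


@pytest.fixture(scope="session")
def fieldm():
    return FieldModel()


@pytest.fixture(scope="session")
def electrode():
    return ElectrodePair()


@pytest.fixture(scope="session")
def reference_axon(fieldm, electrode):
    """A mid-grid 4.4 µm fiber with its unit field and single-pulse AT."""
    axon = make_fiber(4.4, 0.24, 0.14)
    phi = compartment_potentials(axon, fieldm, electrode)
    at = find_activation_threshold(axon, fieldm, 225.0, phi_unit=phi)
    assert np.isfinite(at)
    return {"axon": axon, "phi": phi, "at": at}
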