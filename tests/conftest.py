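import numpy as np
import pytest

from sercakit import HelixSpec, ToyPumpSpec, make_ideal_helix, make_toy_pump
from sercakit.structure import DomainDefinition


@pytest.fixture(scope="session")
def ideal_helix():
    """A 20-residue ideal poly-alanine helix along +z."""
    return make_ideal_helix(HelixSpec(n_residues=20))


@pytest.fixture(scope="session")
def helix_domain():
    return DomainDefinition("helix", ((1, 20),))


@pytest.fixture(scope="session")
def toy_pump():
    """(reference, moved, truth) toy pump with default transforms."""
    return make_toy_pump(ToyPumpSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
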