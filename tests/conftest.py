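import numpy as np
import pytest

from sfps import GeometryConfig, build_model_topology
from sfps.system import Atom, ModelTopology, ROLE_ION, ROLE_WATER_O, \
    SOLVENT_CHAIN


@pytest.fixture(scope="session")
def deka_topology():
    return build_model_topology("DEKA", seed=1)


@pytest.fixture(scope="session")
def dera_topology():
    return build_model_topology("DERA", seed=1)


@pytest.fixture
def tiny_geometry():
    """Small, fast geometry for smoke runs."""
    return GeometryConfig(n_waters=10, box=(20.0, 20.0, 24.0))


def make_free_beads(n, box=(20.0, 20.0, 20.0), charges=None, sigma=3.0,
                    epsilon=0.2, seed=0):
    """Topology of n untethered beads (no walls relevant, no tethers)."""
    rng = np.random.default_rng(seed)
    charges = charges if charges is not None else np.zeros(n)
    atoms = [Atom(i, "X", "BEAD", 1000 + i, SOLVENT_CHAIN, ROLE_WATER_O,
                  float(charges[i]), sigma, epsilon)
             for i in range(n)]
    return ModelTopology(atoms, np.asarray(box, float), "free-beads")


@pytest.fixture
def free_beads_factory():
    return make_free_beads
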