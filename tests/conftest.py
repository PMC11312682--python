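import numpy as np
import pytest

from pairforge import chemio
from pairforge.chemio import AtomRecord, Molecule
from pairforge.energy import assign_parameters


@pytest.fixture(scope="session")
def water_table():
    """Water fixture with bundled-table parameters assigned."""
    return assign_parameters(chemio.fixture("H2O"), backend="table")


@pytest.fixture(scope="session")
def hac():
    return chemio.fixture("HAc")


@pytest.fixture
def make_lj_atom():
    """Factory for single-atom molecules with explicit LJ parameters."""

    def factory(sigma=3.0, epsilon=1.0, charge=0.0, element="Ne",
                coords=(0.0, 0.0, 0.0), name="lj"):
        atom = AtomRecord(element, np.asarray(coords, float), charge=charge,
                          sigma=sigma, epsilon=epsilon)
        return Molecule(name, [atom])

    return factory


@pytest.fixture
def make_lj_pair_molecule():
    """Two-atom rigid LJ 'dumbbell' molecule for toy systems."""

    def factory(separation=1.0, sigma=3.0, epsilon=0.2, element="Ne"):
        a = AtomRecord(element, np.zeros(3), charge=0.0, sigma=sigma,
                       epsilon=epsilon)
        b = AtomRecord(element, np.array([separation, 0.0, 0.0]), charge=0.0,
                       sigma=sigma, epsilon=epsilon)
        return Molecule("dumbbell", [a, b], bonds=[(0, 1)])

    return factory
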