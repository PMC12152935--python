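import numpy as np
import pytest

from vgscan.energy import BackendOptions, ReferenceBackend
from vgscan.fixtures import FixtureSpec, generate_fixture
from vgscan.structmodel import Atom, MolecularSystem


@pytest.fixture(scope="session")
def default_ensemble():
    """The default synthetic complex: 10 seeded snapshots."""
    return generate_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def frame0(default_ensemble):
    return default_ensemble.system_at(0)


@pytest.fixture(scope="session")
def backend():
    return ReferenceBackend()


@pytest.fixture(scope="session")
def fast_backend():
    """Reference backend without the SASA term (cheaper, still physical)."""
    return ReferenceBackend(BackendOptions(gamma_sasa=0.0))


def make_atoms(entries, chain="A", resnum=1, resname="ALA", serial_start=1):
    """entries: list of (name, element, (x, y, z)) for one residue."""
    return [
        Atom(serial_start + i, name, element, np.array(xyz, dtype=float), (chain, resnum, ""), resname)
        for i, (name, element, xyz) in enumerate(entries)
    ]


def two_sided_system(ligand_atoms, receptor_atoms):
    return MolecularSystem(
        ligand_atoms + receptor_atoms, {"A": "ligand", "B": "receptor"}
    )
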