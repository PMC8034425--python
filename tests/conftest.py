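import pytest

from screenkit.molgraph import (
    Atom,
    Bond,
    MoleculeGraph,
    load_fixture,
    perceive,
)


def make_mol(name, elements, bonds, charges=None):
    """Build and perceive a molecule from element symbols and (a, b, order)."""
    atoms = [Atom(element=e) for e in elements]
    if charges:
        for idx, charge in charges.items():
            atoms[idx].formal_charge = charge
    return perceive(
        MoleculeGraph(
            name=name,
            atoms=atoms,
            bonds=[Bond(a, b, o) for a, b, o in bonds],
        )
    )


def benzene_ring(offset=0):
    """Kekule benzene bonds for atoms offset..offset+5."""
    orders = [2, 1, 2, 1, 2, 1]
    return [
        (offset + i, offset + (i + 1) % 6, orders[i]) for i in range(6)
    ]


@pytest.fixture(scope="session")
def nsc765598():
    return load_fixture("nsc765598")


@pytest.fixture(scope="session")
def benzene():
    return load_fixture("benzene")


@pytest.fixture(scope="session")
def water():
    return make_mol("water", ["O"], [])


@pytest.fixture(scope="session")
def phenol():
    return make_mol("phenol", ["C"] * 6 + ["O"], benzene_ring() + [(0, 6, 1)])


@pytest.fixture(scope="session")
def toluene():
    return make_mol("toluene", ["C"] * 7, benzene_ring() + [(0, 6, 1)])


@pytest.fixture(scope="session")
def cyclohexane():
    return make_mol(
        "cyclohexane", ["C"] * 6, [(i, (i + 1) % 6, 1) for i in range(6)]
    )


@pytest.fixture(scope="session")
def hexane():
    return make_mol("n-hexane", ["C"] * 6, [(i, i + 1, 1) for i in range(5)])


@pytest.fixture(scope="session")
def butane():
    return make_mol("n-butane", ["C"] * 4, [(i, i + 1, 1) for i in range(3)])


@pytest.fixture(scope="session")
def ethane():
    return make_mol("ethane", ["C"] * 2, [(0, 1, 1)])


@pytest.fixture(scope="session")
def biphenyl():
    return make_mol(
        "biphenyl",
        ["C"] * 12,
        benzene_ring(0) + benzene_ring(6) + [(0, 6, 1)],
    )


@pytest.fixture(scope="session")
def formamide():
    # H-C(=O)-NH2
    return make_mol("formamide", ["C", "O", "N"], [(0, 1, 2), (0, 2, 1)])
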