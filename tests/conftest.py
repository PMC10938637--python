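import numpy as np
import pytest

from enmix.cg_structures import Bead, BeadStructure
from enmix.topology import AtomRecord, BondedTerm, Topology


@pytest.fixture
def three_bead_structure():
    return BeadStructure(
        [
            Bead(1, "BB", 1, "ALA", (0.0, 0.0, 0.0)),
            Bead(2, "SC1", 1, "ALA", (0.2, 0.1, 0.0)),
            Bead(3, "BB", 2, "GLY", (0.35, 0.0, 0.0)),
        ],
        title="three beads",
    )


def make_topology(bond_params, rubber_params, name="mol", atoms=5, angles=(), charges=None):
    """Helper: compact topology constructor for mixing tests.

    ``bond_params``/``rubber_params``: {(i, j): (b0, k)}.
    ``angles``: iterable of (i, j, k, funct, theta0, fc).
    """
    charges = charges or {}
    records = [
        AtomRecord(i, "P1", (i + 1) // 2, "ALA", "BB" if i % 2 else "SC1",
                   charges.get(i, 0.0))
        for i in range(1, atoms + 1)
    ]
    bonded = []
    for (i, j), (b0, k) in sorted(bond_params.items()):
        bonded.append(BondedTerm((i, j), 1, (b0, k), "bonds"))
    for (i, j), (b0, k) in sorted(rubber_params.items()):
        bonded.append(BondedTerm((i, j), 6, (b0, k), "rubber_band"))
    for (i, j, k3, funct, theta0, fc) in angles:
        bonded.append(BondedTerm((i, j, k3), funct, (theta0, fc), "angles"))
    top = Topology(molecule_name=name, nrexcl=1, atoms=records, bonded=bonded)
    top.validate()
    return top


@pytest.fixture
def rng():
    return np.random.default_rng(42)
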