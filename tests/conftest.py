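import pytest

from prorigid import (
    build_ethane,
    build_ideal_helix,
    detect_hbonds,
    detect_hydrophobics_legacy,
    detect_hydrophobics_lj,
    infer_covalent_bonds,
)
from prorigid.decomposition import Decomposition, ResidueItem


@pytest.fixture(scope="session")
def ethane():
    return build_ethane()


@pytest.fixture(scope="session")
def ethane_bonds(ethane):
    return infer_covalent_bonds(ethane)


@pytest.fixture(scope="session")
def helix18():
    return build_ideal_helix(18)


@pytest.fixture(scope="session")
def helix18_bonds(helix18):
    return infer_covalent_bonds(helix18)


@pytest.fixture(scope="session")
def helix18_hbonds(helix18, helix18_bonds):
    return detect_hbonds(helix18, helix18_bonds)


@pytest.fixture(scope="session")
def helix18_lj(helix18, helix18_bonds):
    return detect_hydrophobics_lj(helix18, helix18_bonds)


@pytest.fixture(scope="session")
def helix18_legacy(helix18, helix18_bonds):
    return detect_hydrophobics_legacy(helix18, helix18_bonds)


@pytest.fixture(scope="session")
def gold_10res():
    """Gold standard partition {1-5}, {6,7}, {8,9,10} over residues 1-10."""
    return Decomposition.from_clusters([
        [ResidueItem("A", i) for i in range(1, 6)],
        [ResidueItem("A", 6), ResidueItem("A", 7)],
        [ResidueItem("A", i) for i in range(8, 11)],
    ])
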