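from __future__ import annotations

import networkx as nx
import pytest

from itsrules.chemio import (
    FIXTURE_FAMILIES,
    generate_fixture_set,
    parse_mapped_reaction,
)
from itsrules.its_core import build_its

ESTERIFICATION = (
    "[C:1](=[O:2])([O:3][H:4])[CH3:5].[O:6]([H:7])[CH3:8]"
    ">>[C:1](=[O:2])([O:6][CH3:8])[CH3:5].[O:3]([H:4])[H:7]"
)
DIELS_ALDER = (
    "[CH2:1]=[CH:2][CH:3]=[CH2:4].[CH2:5]=[CH2:6]"
    ">>[CH2:1]1[CH:2]=[CH:3][CH2:4][CH2:5][CH2:6]1"
)
HYDROGENATION_PARTIAL = "[CH2:1]=[CH2:2].[H][H]>>[CH3:1][CH3:2]"
IDENTITY = "[CH3:1][OH:2]>>[CH3:1][OH:2]"


@pytest.fixture(scope="session")
def fixture_pairs():
    """(family, mapped SMILES) pairs: 4 reactions per mechanism family."""
    return generate_fixture_set(FIXTURE_FAMILIES, 4, 101)


@pytest.fixture(scope="session")
def fixture_reactions(fixture_pairs):
    return [(fam, parse_mapped_reaction(smi)) for fam, smi in fixture_pairs]


@pytest.fixture(scope="session")
def fixture_its(fixture_reactions):
    """(index, family, ITS graph) per fixture reaction."""
    return [(i, fam, build_its(rxn)) for i, (fam, rxn) in enumerate(fixture_reactions)]


def molecule_match(a: dict, b: dict) -> bool:
    return (
        a["element"] == b["element"]
        and a["charge"] == b["charge"]
        and a["hcount"] == b["hcount"]
    )


def order_match(a: dict, b: dict) -> bool:
    return a["order"] == b["order"]


def assert_molecules_isomorphic(a: nx.Graph, b: nx.Graph) -> None:
    assert nx.is_isomorphic(a, b, node_match=molecule_match, edge_match=order_match)
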