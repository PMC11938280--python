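"""Reaction SMILES parsing/writing, canonical keys, and synthetic fixtures.

Molecular graphs are :class:`networkx.Graph` objects with node attributes

``element``
    periodic-table symbol (``"C"``, ``"H"``, ...)
``charge``
    integer formal charge
``hcount``
    number of attached hydrogens folded into the vertex (implicit plus
    explicit-but-unmapped hydrogens)
``map``
    atom-map number, ``0`` when absent
``aromatic``
    aromaticity flag as perceived before kekulization

and edge attribute ``order`` in ``{1, 2, 3}`` (bond orders are read after
deterministic kekulization; the aromatic flag survives on the vertices).

Explicit hydrogens that carry a map number — the mechanistically relevant
ones — are kept as first-class vertices.  Explicit hydrogens without a map
number are folded into the neighbouring heavy atom's ``hcount``, except when
they form an all-hydrogen molecule (H–H, a lone hydride) which is retained as
its own component.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass
from typing import Iterator, Sequence

import networkx as nx
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
}
_ORDER_BOND = {v: k for k, v in _BOND_ORDER.items()}


class ReactionParseError(ValueError):
    """Malformed reaction SMILES."""


class ReactionValidationError(ValueError):
    """Structurally valid SMILES violating a reaction-level contract."""


# ---------------------------------------------------------------------------
# data types


@dataclass
class MappedReaction:
    """A reaction G -> H with a (possibly partial) atom map alpha.

    ``mapping`` sends reactant node ids to product node ids; it is injective
    and element-preserving.  ``complete`` means alpha is a bijection over all
    retained vertices of both sides (explicit-H vertices included);
    ``balanced`` means per-element atom counts, hydrogens included, agree
    between the two sides.
    """

    reactants: nx.Graph
    products: nx.Graph
    mapping: dict[int, int]
    balanced: bool = False
    complete: bool = False

    def __post_init__(self) -> None:
        self.balanced = _is_balanced(self.reactants, self.products)
        self.complete = len(self.mapping) == self.reactants.number_of_nodes() == self.products.number_of_nodes()


def _element_counts(g: nx.Graph) -> Counter:
    counts: Counter = Counter()
    for _, d in g.nodes(data=True):
        counts[d["element"]] += 1
        counts["H"] += d.get("hcount", 0)
    return counts


def _is_balanced(g: nx.Graph, h: nx.Graph) -> bool:
    return _element_counts(g) == _element_counts(h)


# ---------------------------------------------------------------------------
# parsing


def _side_to_graph(smiles: str) -> nx.Graph:
    """Parse one side of a reaction SMILES into a molecular graph."""
    if smiles == "":
        return nx.Graph()
    params = Chem.SmilesParserParams()
    params.removeHs = False  # mapped hydrogens are first-class vertices
    mol = Chem.MolFromSmiles(smiles, params)
    if mol is None:
        raise ReactionParseError(f"cannot parse SMILES fragment {smiles!r}")
    aromatic = {a.GetIdx(): a.GetIsAromatic() for a in mol.GetAtoms()}
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except Chem.KekulizeException as exc:  # pragma: no cover - rdkit guards
        raise ReactionParseError(f"cannot kekulize {smiles!r}: {exc}") from exc

    seen_maps: set[int] = set()
    for atom in mol.GetAtoms():
        m = atom.GetAtomMapNum()
        if m:
            if m in seen_maps:
                raise ReactionValidationError(
                    f"duplicate atom-map number {m} within one side: {smiles!r}"
                )
            seen_maps.add(m)

    g = nx.Graph()
    fold: dict[int, int] = {}  # rdkit idx of folded H -> heavy neighbour idx
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "H" and atom.GetAtomMapNum() == 0:
            heavy = [n for n in atom.GetNeighbors() if n.GetSymbol() != "H"]
            if heavy:
                fold[atom.GetIdx()] = heavy[0].GetIdx()
                continue
        g.add_node(
            atom.GetIdx(),
            element=atom.GetSymbol(),
            charge=atom.GetFormalCharge(),
            hcount=atom.GetTotalNumHs(),
            map=atom.GetAtomMapNum(),
            aromatic=aromatic[atom.GetIdx()],
        )
    for idx, heavy_idx in fold.items():
        g.nodes[heavy_idx]["hcount"] += 1
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in fold or j in fold:
            continue
        order = _BOND_ORDER.get(bond.GetBondType())
        if order is None:
            raise ReactionParseError(
                f"unsupported bond type {bond.GetBondType()} in {smiles!r}"
            )
        g.add_edge(i, j, order=order)
    return g


def parse_mapped_reaction(line: str) -> MappedReaction:
    """Parse one reaction-SMILES line ``reactants>agents>products``.

    Atoms carrying equal map numbers on the two sides are paired by alpha;
    a map number present on one side only leaves that atom unmapped (partial
    alpha).  The agents segment is parsed for syntax but otherwise ignored.
    """
    parts = line.strip().split(">")
    if len(parts) == 2:
        parts = [parts[0], "", parts[1]]
    if len(parts) != 3:
        raise ReactionParseError(
            f"expected 'reactants>agents>products' with two '>' separators: {line!r}"
        )
    g = _side_to_graph(parts[0])
    h = _side_to_graph(parts[2])
    g_by_map = {d["map"]: n for n, d in g.nodes(data=True) if d["map"]}
    h_by_map = {d["map"]: n for n, d in h.nodes(data=True) if d["map"]}
    mapping = {g_by_map[m]: h_by_map[m] for m in g_by_map.keys() & h_by_map.keys()}
    return MappedReaction(reactants=g, products=h, mapping=mapping)


def iter_reaction_lines(text: str) -> Iterator[str]:
    """Yield non-empty, non-comment reaction lines from a text blob."""
    for raw in text.splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            yield line


# ---------------------------------------------------------------------------
# writing


def _graph_to_mol(g: nx.Graph, maps: dict[int, int]) -> Chem.Mol:
    rw = Chem.RWMol()
    idx: dict[int, int] = {}
    for n in sorted(g.nodes):
        d = g.nodes[n]
        atom = Chem.Atom(d["element"])
        atom.SetFormalCharge(d.get("charge", 0))
        atom.SetNoImplicit(True)
        atom.SetNumExplicitHs(d.get("hcount", 0))
        atom.SetAtomMapNum(maps.get(n, 0))
        idx[n] = rw.AddAtom(atom)
    for u, v, d in g.edges(data=True):
        rw.AddBond(idx[u], idx[v], _ORDER_BOND[d["order"]])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def write_reaction(rxn: MappedReaction) -> str:
    """Serialize a reaction to canonical mapped SMILES (``G>>H``).

    Mapped atom pairs receive equal map numbers on the two sides; unmapped
    atoms (spectators, free hydrogens) are emitted without map numbers.  The
    output re-parses to a reaction isomorphic to the input.
    """
    if rxn.products.number_of_nodes() == 0:
        raise ReactionValidationError("refusing to write a reaction with no products")
    if rxn.reactants.number_of_nodes() == 0:
        raise ReactionValidationError("refusing to write a reaction with no reactants")
    g_maps: dict[int, int] = {}
    h_maps: dict[int, int] = {}
    for i, (gn, hn) in enumerate(sorted(rxn.mapping.items()), start=1):
        g_maps[gn] = i
        h_maps[hn] = i
    left = Chem.MolToSmiles(_graph_to_mol(rxn.reactants, g_maps), canonical=True)
    right = Chem.MolToSmiles(_graph_to_mol(rxn.products, h_maps), canonical=True)
    return f"{left}>>{right}"


# ---------------------------------------------------------------------------
# canonical keys


_EMPTY_KEY = "empty-graph"


def _attr_string(d: dict) -> str:
    if isinstance(d.get("hcount"), tuple):
        # ITS vertex: mirror the isomorphism semantics — element, charge
        # pair, and the hydrogen-count *change* (absolute counts are
        # context, not mechanism)
        return f"{d['element']}|{d['charge']}|{d['hcount'][1] - d['hcount'][0]}"
    return "|".join(f"{k}={d[k]}" for k in sorted(d) if not k.startswith("_"))


def canonical_key(g: nx.Graph) -> str:
    """Isomorphism-invariant hash key for a labeled graph.

    Equal keys are necessary but not sufficient for isomorphism: the key is a
    bucket prefilter (Weisfeiler–Lehman hash over all node/edge attributes),
    never an isomorphism decision.
    """
    if g.number_of_nodes() == 0:
        return _EMPTY_KEY
    tagged = nx.Graph()
    for n, d in g.nodes(data=True):
        tagged.add_node(n, _wl=_attr_string(d))
    for u, v, d in g.edges(data=True):
        tagged.add_edge(u, v, _wl=_attr_string(d))
    return nx.weisfeiler_lehman_graph_hash(
        tagged, node_attr="_wl", edge_attr="_wl", iterations=3
    )


# ---------------------------------------------------------------------------
# synthetic fixtures
#
# Each family is a balanced, completely mapped single-step core transformation
# (with mechanistic hydrogens explicit and mapped) plus substitution slots
# where randomly drawn substituents replace a hydrogen identically on both
# sides.  All members of a family therefore share an isomorphic reaction
# center while differing in context.


@dataclass(frozen=True)
class _Core:
    # atoms: tag -> (element, hcount_G, hcount_H)
    atoms: dict[str, tuple[str, int, int]]
    # edges: (tag, tag) -> (order_G, order_H); 0 = absent on that side
    edges: dict[tuple[str, str], tuple[int, int]]
    # tags where one substituent may replace one hydrogen (must have h >= 1
    # on both sides)
    slots: tuple[str, ...]


_FAMILIES: dict[str, _Core] = {
    "hydrogenation": _Core(
        atoms={"C1": ("C", 2, 2), "C2": ("C", 2, 2), "H3": ("H", 0, 0), "H4": ("H", 0, 0)},
        edges={
            ("C1", "C2"): (2, 1),
            ("H3", "H4"): (1, 0),
            ("C1", "H3"): (0, 1),
            ("C2", "H4"): (0, 1),
        },
        slots=("C1", "C2"),
    ),
    "diels_alder": _Core(
        atoms={
            "C1": ("C", 2, 2),
            "C2": ("C", 1, 1),
            "C3": ("C", 1, 1),
            "C4": ("C", 2, 2),
            "C5": ("C", 2, 2),
            "C6": ("C", 2, 2),
        },
        edges={
            ("C1", "C2"): (2, 1),
            ("C2", "C3"): (1, 2),
            ("C3", "C4"): (2, 1),
            ("C5", "C6"): (2, 1),
            ("C1", "C6"): (0, 1),
            ("C4", "C5"): (0, 1),
        },
        slots=("C1", "C4", "C5", "C6"),
    ),
    "esterification": _Core(
        atoms={
            "C1": ("C", 1, 1),
            "O2": ("O", 0, 0),
            "O3": ("O", 0, 0),
            "H4": ("H", 0, 0),
            "O6": ("O", 0, 0),
            "H7": ("H", 0, 0),
            "C8": ("C", 3, 3),
        },
        edges={
            ("C1", "O2"): (2, 2),
            ("C1", "O3"): (1, 0),
            ("O3", "H4"): (1, 1),
            ("O6", "H7"): (1, 0),
            ("C1", "O6"): (0, 1),
            ("O3", "H7"): (0, 1),
            ("O6", "C8"): (1, 1),
        },
        slots=("C1", "C8"),
    ),
    "substitution": _Core(
        atoms={
            "C1": ("C", 3, 3),
            "Cl2": ("Cl", 0, 0),
            "O3": ("O", 0, 0),
            "H4": ("H", 0, 0),
            "C5": ("C", 3, 3),
        },
        edges={
            ("C1", "Cl2"): (1, 0),
            ("O3", "H4"): (1, 0),
            ("C1", "O3"): (0, 1),
            ("Cl2", "H4"): (0, 1),
            ("O3", "C5"): (1, 1),
        },
        slots=("C1", "C5"),
    ),
    "amide_formation": _Core(
        atoms={
            "C1": ("C", 1, 1),
            "O2": ("O", 0, 0),
            "O3": ("O", 0, 0),
            "H4": ("H", 0, 0),
            "N5": ("N", 2, 2),
            "H6": ("H", 0, 0),
        },
        edges={
            ("C1", "O2"): (2, 2),
            ("C1", "O3"): (1, 0),
            ("O3", "H4"): (1, 1),
            ("N5", "H6"): (1, 0),
            ("C1", "N5"): (0, 1),
            ("O3", "H6"): (0, 1),
        },
        slots=("C1", "N5"),
    ),
}

FIXTURE_FAMILIES: tuple[str, ...] = tuple(sorted(_FAMILIES))

# substituent alphabet: chains of (element, hcount) attached by single bonds,
# identical on both sides; None leaves the hydrogen in place
_SUBSTITUENTS: tuple[tuple[tuple[str, int], ...] | None, ...] = (
    None,
    (("C", 3),),                       # methyl
    (("C", 2), ("C", 3)),              # ethyl
    (("C", 2), ("C", 2), ("C", 3)),    # propyl
    (("C", 2), ("O", 1)),              # hydroxymethyl
    (("C", 2), ("F", 0)),              # fluoromethyl
)


def _build_family_reaction(core: _Core, rng: random.Random) -> MappedReaction:
    g = nx.Graph()
    h = nx.Graph()
    mapping: dict[int, int] = {}
    node_of: dict[str, int] = {}
    nid = 0
    for tag, (el, hg, hh) in core.atoms.items():
        g.add_node(nid, element=el, charge=0, hcount=hg, map=nid + 1, aromatic=False)
        h.add_node(nid, element=el, charge=0, hcount=hh, map=nid + 1, aromatic=False)
        mapping[nid] = nid
        node_of[tag] = nid
        nid += 1
    for (a, b), (og, oh) in core.edges.items():
        if og:
            g.add_edge(node_of[a], node_of[b], order=og)
        if oh:
            h.add_edge(node_of[a], node_of[b], order=oh)
    for tag in core.slots:
        sub = rng.choice(_SUBSTITUENTS)
        if sub is None:
            continue
        anchor = node_of[tag]
        if g.nodes[anchor]["hcount"] < 1 or h.nodes[anchor]["hcount"] < 1:
            continue
        g.nodes[anchor]["hcount"] -= 1
        h.nodes[anchor]["hcount"] -= 1
        prev = anchor
        for el, hc in sub:
            g.add_node(nid, element=el, charge=0, hcount=hc, map=nid + 1, aromatic=False)
            h.add_node(nid, element=el, charge=0, hcount=hc, map=nid + 1, aromatic=False)
            mapping[nid] = nid
            g.add_edge(prev, nid, order=1)
            h.add_edge(prev, nid, order=1)
            prev = nid
            nid += 1
    return MappedReaction(reactants=g, products=h, mapping=mapping)


def generate_fixtures(family: str, n: int, seed: int) -> list[str]:
    """Generate ``n`` balanced, completely mapped single-step reactions.

    All reactions of one family share an isomorphic reaction center; the
    surrounding context varies through randomly drawn substituents.  Output
    is deterministic in ``(family, n, seed)``.
    """
    if family not in _FAMILIES:
        raise ValueError(
            f"unknown family {family!r}; valid families: {', '.join(FIXTURE_FAMILIES)}"
        )
    core = _FAMILIES[family]
    rng = random.Random(seed * 1000003 + FIXTURE_FAMILIES.index(family))
    return [write_reaction(_build_family_reaction(core, rng)) for _ in range(n)]


def generate_fixture_set(
    families: Sequence[str], n_per_family: int, seed: int
) -> list[tuple[str, str]]:
    """Generate ``(family, reaction_smiles)`` pairs across several families."""
    out: list[tuple[str, str]] = []
    for fam in families:
        for line in generate_fixtures(fam, n_per_family, seed):
            out.append((fam, line))
    return out
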