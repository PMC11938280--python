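"""Equivalence of atom–atom maps and ensemble consensus.

Two AAMs of the same reaction are equivalent exactly when their ITS graphs
are isomorphic (label-preserving, over the attribute pairs).  For partial
maps that cover the reaction center, the efficiently testable approximate
condition compares radius-r extended reaction centers instead; it is
necessary but not sufficient, with false positives known to be rare on
chemical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
from .chemio import MappedReaction, write_reaction
from .its_core import build_its, template_for

# counter of VF2 isomorphism calls, used to verify the hierarchical-clustering
# efficiency claim; incremented by its_isomorphic
ISO_CALLS = {"count": 0}


class BadMappingError(ValueError):
    """A partial map leaves part of the reaction center unmapped."""


def _node_match(a: dict, b: dict) -> bool:
    # Hydrogen counts are compared as the change h_H - h_G, not absolutely:
    # the mechanism is the same whether the reacting carbon carries two
    # hydrogens or one (substitution outside the center must not split
    # isomorphism classes); the moved hydrogens themselves are explicit
    # vertices after completion.
    return (
        a["element"] == b["element"]
        and a["charge"] == b["charge"]
        and a["hcount"][1] - a["hcount"][0] == b["hcount"][1] - b["hcount"][0]
    )


def _edge_match(a: dict, b: dict) -> bool:
    return a["order"] == b["order"]


def its_isomorphic(a: nx.Graph, b: nx.Graph) -> bool:
    """Label-preserving isomorphism of two ITS graphs (VF2).

    Matches element, charge pair and hydrogen-count change on vertices and
    the bond-order pair on edges.
    """
    ISO_CALLS["count"] += 1
    if a.number_of_nodes() != b.number_of_nodes() or a.number_of_edges() != b.number_of_edges():
        return False
    return nx.is_isomorphic(a, b, node_match=_node_match, edge_match=_edge_match)


def _check_center_mapped(rxn: MappedReaction) -> None:
    """Reject partial maps whose unmapped part touches a changed bond.

    For every mapped vertex, the multiset of (bond order, partner element)
    towards unmapped atoms must agree between the two sides; otherwise a
    changed edge is incident to an unmapped atom and the map does not cover
    the reaction center ('good' partial-map condition unmet).
    """
    mapped_g = set(rxn.mapping)
    mapped_h = set(rxn.mapping.values())
    for gn, hn in rxn.mapping.items():
        dangling_g = sorted(
            (d["order"], rxn.reactants.nodes[v if u == gn else u]["element"])
            for u, v, d in rxn.reactants.edges(gn, data=True)
            if (v if u == gn else u) not in mapped_g
        )
        dangling_h = sorted(
            (d["order"], rxn.products.nodes[v if u == hn else u]["element"])
            for u, v, d in rxn.products.edges(hn, data=True)
            if (v if u == hn else u) not in mapped_h
        )
        if dangling_g != dangling_h:
            raise BadMappingError(
                f"partial map leaves a changed bond at mapped atom {gn} uncovered"
            )


def aam_equivalent(a: MappedReaction, b: MappedReaction, r: int = 1) -> bool:
    """Decide equivalence of two atom–atom maps of the same reaction.

    Complete maps are compared by full-ITS isomorphism.  Partial maps are
    compared by isomorphism of their radius-``r`` extended reaction centers —
    the approximate condition, necessary but not sufficient for consistency.
    """
    if a.complete and b.complete:
        return its_isomorphic(build_its(a), build_its(b))
    _check_center_mapped(a)
    _check_center_mapped(b)
    ta = template_for(build_its(a, allow_partial=True), r)
    tb = template_for(build_its(b, allow_partial=True), r)
    return its_isomorphic(ta.graph, tb.graph)


@dataclass
class ConsensusResult:
    status: str  # consensus | disagreement | incomplete
    representative: nx.Graph | None
    agreement_matrix: list[list[bool]]
    policy: str
    winning_sources: list[int]


def _unmapped_key(rxn: MappedReaction) -> tuple[str, str]:
    """Canonical unmapped SMILES of the two sides."""
    stripped = MappedReaction(
        reactants=rxn.reactants, products=rxn.products, mapping=dict(rxn.mapping)
    )
    smi = write_reaction(stripped)
    left, right = smi.split(">>")

    def strip(s: str) -> str:
        import re

        return re.sub(r":\d+(?=[\]])", "", s)

    from rdkit import Chem

    cl = Chem.CanonSmiles(strip(left))
    cr = Chem.CanonSmiles(strip(right))
    return cl, cr


def ensemble_consensus(
    sources: list[MappedReaction], policy: str = "strict", r: int = 1
) -> ConsensusResult:
    """Consensus over several independently mapped versions of one reaction.

    ``strict``: consensus iff all pairs are equivalent.  ``majority``:
    consensus iff a strict majority of the sources forms one equivalence
    class.  The representative is the ITS of the first member (in input
    order) of the winning class.
    """
    if policy not in ("strict", "majority"):
        raise ValueError("policy must be 'strict' or 'majority'")
    if len(sources) < 2:
        raise ValueError("consensus needs at least two sources")
    keys = {_unmapped_key(s) for s in sources}
    if len(keys) > 1:
        raise ValueError("sources do not describe the same unmapped reaction")

    n = len(sources)
    matrix = [[True] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            eq = aam_equivalent(sources[i], sources[j], r=r)
            matrix[i][j] = matrix[j][i] = eq

    # greedy equivalence classes by first representative
    classes: list[list[int]] = []
    for i in range(n):
        for cls in classes:
            if matrix[cls[0]][i]:
                cls.append(i)
                break
        else:
            classes.append([i])

    def rep(cls: list[int]) -> nx.Graph:
        first = sources[cls[0]]
        return build_its(first, allow_partial=not first.complete)

    if policy == "strict":
        if len(classes) == 1:
            return ConsensusResult("consensus", rep(classes[0]), matrix, policy, classes[0])
        return ConsensusResult("disagreement", None, matrix, policy, [])
    winner = max(classes, key=len)
    if 2 * len(winner) > n:
        return ConsensusResult("consensus", rep(winner), matrix, policy, winner)
    return ConsensusResult("disagreement", None, matrix, policy, [])
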