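"""Imaginary transition state (ITS) graphs, reaction centers, templates.

The ITS graph superimposes reactant graph G and product graph H through the
atom map: every mapped atom pair becomes one vertex carrying attribute pairs
``(value in G, value in H)``, and every bond present on either side becomes
one edge carrying the bond-order pair ``(o_G, o_H)`` with ``0`` marking
absence of the bond on that side.  The reaction center is the subgraph of
edges whose order pair differs plus all vertices with a hydrogen-count or
charge change; templates are radius-r neighbourhoods of the center.

Node attributes of an ITS graph: ``element`` (str), ``charge`` (int pair),
``hcount`` (int pair), ``aromatic`` (bool pair).  Edge attribute: ``order``
(int pair).  Graph attributes ``free_h_reactant`` / ``free_h_product`` count
hydrogens sitting in unmapped all-hydrogen components (e.g. an unmapped H2
donor) on either side; they feed hydrogen completion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx

from .chemio import MappedReaction

logger = logging.getLogger(__name__)

#: ITS graphs are plain NetworkX graphs with pair-valued attributes; the
#: alias documents intent in signatures.
ITSGraph = nx.Graph


class MappingIntegrityError(ValueError):
    """The atom map pairs atoms that cannot correspond."""


@dataclass
class Template:
    """A partial ITS: the reaction center extended to graph radius ``r``.

    ``graph`` is an ITS-labeled graph; ``center_nodes`` marks the embedded
    reaction center; ``radius`` is the extension radius (0 = bare center).
    """

    graph: nx.Graph
    radius: int
    center_nodes: frozenset = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# construction


def build_its(rxn: MappedReaction, allow_partial: bool = False) -> nx.Graph:
    """Construct the ITS graph of a mapped reaction in linear time.

    Vertices are the mapped atom pairs.  With ``allow_partial`` the map may
    miss atoms: the ITS is then restricted to the mapped atoms and edges to
    unmapped atoms are dropped with a warning.  Unmapped components made of
    hydrogen only (H2 donors/acceptors) are never an error; their hydrogen
    count is recorded on the graph for later completion.
    """
    g, h, alpha = rxn.reactants, rxn.products, rxn.mapping
    mapped_g = set(alpha)
    mapped_h = set(alpha.values())

    free_h_g, unmapped_heavy_g = _free_hydrogen_components(g, mapped_g)
    free_h_h, unmapped_heavy_h = _free_hydrogen_components(h, mapped_h)
    if (unmapped_heavy_g or unmapped_heavy_h) and not allow_partial:
        raise MappingIntegrityError(
            "atom map does not cover all heavy atoms; pass allow_partial=True "
            "for a partial ITS restricted to mapped atoms"
        )

    its = nx.Graph(free_h_reactant=free_h_g, free_h_product=free_h_h)
    for gn, hn in alpha.items():
        dg, dh = g.nodes[gn], h.nodes[hn]
        if dg["element"] != dh["element"]:
            raise MappingIntegrityError(
                f"map pairs {dg['element']} with {dh['element']}"
            )
        its.add_node(
            gn,
            element=dg["element"],
            charge=(dg["charge"], dh["charge"]),
            hcount=(dg["hcount"], dh["hcount"]),
            aromatic=(dg["aromatic"], dh["aromatic"]),
        )
    inv = {hn: gn for gn, hn in alpha.items()}
    for u, v, d in g.edges(data=True):
        if u in mapped_g and v in mapped_g:
            its.add_edge(u, v, order=(d["order"], 0))
        elif u in mapped_g or v in mapped_g:
            logger.warning("dropping reactant edge (%s,%s) incident to unmapped atom", u, v)
    for u, v, d in h.edges(data=True):
        if u in mapped_h and v in mapped_h:
            gu, gv = inv[u], inv[v]
            if its.has_edge(gu, gv):
                og, _ = its.edges[gu, gv]["order"]
                its.edges[gu, gv]["order"] = (og, d["order"])
            else:
                its.add_edge(gu, gv, order=(0, d["order"]))
        elif u in mapped_h or v in mapped_h:
            logger.warning("dropping product edge (%s,%s) incident to unmapped atom", u, v)
    return its


def _free_hydrogen_components(g: nx.Graph, mapped: set) -> tuple[tuple[int, ...], int]:
    """Sizes of unmapped all-H components, plus count of unmapped heavy atoms."""
    sizes: list[int] = []
    unmapped_heavy = 0
    for comp in nx.connected_components(g):
        if comp & mapped:
            unmapped_heavy += sum(
                1 for n in comp if n not in mapped and g.nodes[n]["element"] != "H"
            )
            continue
        if all(g.nodes[n]["element"] == "H" for n in comp):
            sizes.append(len(comp))
        else:
            unmapped_heavy += sum(1 for n in comp if g.nodes[n]["element"] != "H")
    return tuple(sorted(sizes)), unmapped_heavy


# ---------------------------------------------------------------------------
# reaction center and extension


def changed_edges(its: nx.Graph) -> list[tuple]:
    return [(u, v) for u, v, d in its.edges(data=True) if d["order"][0] != d["order"][1]]


def changed_vertices(its: nx.Graph) -> set:
    out = set()
    for u, v in changed_edges(its):
        out.add(u)
        out.add(v)
    for n, d in its.nodes(data=True):
        if d["hcount"][0] != d["hcount"][1] or d["charge"][0] != d["charge"][1]:
            out.add(n)
    return out


def reaction_center(its: nx.Graph) -> nx.Graph:
    """Extract the reaction center: changed edges, their endpoints, and
    vertices with a hydrogen-count or charge change.  May be empty."""
    nodes = changed_vertices(its)
    center = nx.Graph(**its.graph)
    for n in nodes:
        center.add_node(n, **its.nodes[n])
    for u, v in changed_edges(its):
        center.add_edge(u, v, **its.edges[u, v])
    return center


def extend_center(its: nx.Graph, center: nx.Graph, r: int) -> Template:
    """Build the radius-``r`` template: all ITS vertices within graph
    distance ``r`` of the center (distance measured over all ITS edges,
    including one-sided ones) plus every ITS edge among them."""
    if r < 0:
        raise ValueError("radius must be non-negative")
    if r == 0:
        nodes = set(center.nodes)
    else:
        nodes = set(center.nodes)
        frontier = set(center.nodes)
        for _ in range(r):
            frontier = {m for n in frontier for m in its.neighbors(n)} - nodes
            if not frontier:
                break
            nodes |= frontier
    sub = nx.Graph(**its.graph)
    for n in nodes:
        sub.add_node(n, **its.nodes[n])
    if r == 0:
        sub.add_edges_from((u, v, d) for u, v, d in center.edges(data=True))
    else:
        for u, v, d in its.subgraph(nodes).edges(data=True):
            sub.add_edge(u, v, **d)
    return Template(graph=sub, radius=r, center_nodes=frozenset(center.nodes))


def template_for(its: nx.Graph, r: int) -> Template:
    """Convenience: reaction center extended to radius ``r``."""
    return extend_center(its, reaction_center(its), r)


# ---------------------------------------------------------------------------
# reversal


def reverse_its(its: nx.Graph) -> nx.Graph:
    """Reverse the reaction: swap the two components of every pair label."""
    out = nx.Graph(
        free_h_reactant=its.graph.get("free_h_product", ()),
        free_h_product=its.graph.get("free_h_reactant", ()),
    )
    for n, d in its.nodes(data=True):
        out.add_node(
            n,
            element=d["element"],
            charge=(d["charge"][1], d["charge"][0]),
            hcount=(d["hcount"][1], d["hcount"][0]),
            aromatic=(d["aromatic"][1], d["aromatic"][0]),
        )
    for u, v, d in its.edges(data=True):
        out.add_edge(u, v, order=(d["order"][1], d["order"][0]))
    return out


# ---------------------------------------------------------------------------
# projections


def project(its: nx.Graph, side: int) -> nx.Graph:
    """Project the ITS onto one side (0 = reactants, 1 = products).

    Returns a molecular graph with scalar node/edge attributes; edges absent
    on the requested side are dropped.
    """
    if side not in (0, 1):
        raise ValueError("side must be 0 (reactants) or 1 (products)")
    mol = nx.Graph()
    for n, d in its.nodes(data=True):
        mol.add_node(
            n,
            element=d["element"],
            charge=d["charge"][side],
            hcount=d["hcount"][side],
            map=0,
            aromatic=d["aromatic"][side],
        )
    for u, v, d in its.edges(data=True):
        if d["order"][side]:
            mol.add_edge(u, v, order=d["order"][side])
    return mol


# ---------------------------------------------------------------------------
# JSON serialization


def its_to_json(its: nx.Graph, radius: int | None = None, center_nodes=None) -> str:
    doc = {
        "free_h_reactant": list(its.graph.get("free_h_reactant", ())),
        "free_h_product": list(its.graph.get("free_h_product", ())),
        "vertices": [
            {
                "id": int(n),
                "element": d["element"],
                "charge": list(d["charge"]),
                "hcount": list(d["hcount"]),
                "aromatic": list(d["aromatic"]),
            }
            for n, d in sorted(its.nodes(data=True))
        ],
        "edges": [
            {"u": int(u), "v": int(v), "order": list(d["order"])}
            for u, v, d in sorted(its.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1])))
        ],
    }
    if radius is not None:
        doc["radius"] = radius
    if center_nodes is not None:
        doc["center"] = sorted(int(n) for n in center_nodes)
    return json.dumps(doc, sort_keys=True)


def its_from_json(text: str) -> nx.Graph | Template:
    doc = json.loads(text)
    g = nx.Graph(
        free_h_reactant=tuple(doc.get("free_h_reactant", ())),
        free_h_product=tuple(doc.get("free_h_product", ())),
    )
    for v in doc["vertices"]:
        g.add_node(
            v["id"],
            element=v["element"],
            charge=tuple(v["charge"]),
            hcount=tuple(v["hcount"]),
            aromatic=tuple(v["aromatic"]),
        )
    for e in doc["edges"]:
        g.add_edge(e["u"], e["v"], order=tuple(e["order"]))
    if "radius" in doc:
        return Template(
            graph=g,
            radius=doc["radius"],
            center_nodes=frozenset(doc.get("center", [])),
        )
    return g
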