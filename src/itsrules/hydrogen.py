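"""Mechanistic hydrogen completion of partial ITS graphs.

Atom-mapping tools rarely map hydrogens, yet many mechanisms move them.  The
ITS records, per vertex, the hydrogen count on each side; a nonzero
difference marks a donor (loses hydrogens towards the products) or an
acceptor (gains them).  Completion materializes each transferred hydrogen as
an explicit vertex with one reactant-side incidence (order pair ``(1, 0)``)
and one product-side incidence (``(0, 1)``), enumerating every pairing of
donor hydrogens with acceptor sites.  A single transferred pair always has a
unique completion; with several pairs the number of combinations grows
factorially and distinct pairings may yield non-isomorphic reaction centers,
in which case the completion is ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import networkx as nx

from .aam_consensus import its_isomorphic
from .chemio import canonical_key

DEFAULT_CAP = 64


@dataclass(frozen=True)
class HydrogenDelta:
    vertex: int
    delta: int  # h_H - h_G, never zero


@dataclass
class CompletionResult:
    """Outcome of hydrogen completion.

    status: ``unique`` (all pairings isomorphic; one representative),
    ``ambiguous`` (non-isomorphic candidates, all returned), ``unbalanced``
    (donated and accepted hydrogens do not cancel), ``overflow`` (pairing
    count exceeded the cap).
    """

    status: str
    completions: list[nx.Graph] = field(default_factory=list)
    n_pairings: int = 0

    @property
    def representative(self) -> nx.Graph | None:
        return self.completions[0] if self.completions else None


def hydrogen_deltas(its: nx.Graph) -> list[HydrogenDelta]:
    """Per-vertex hydrogen-count changes, ascending by vertex id.

    Unmapped all-hydrogen molecules (an H2 donor or product) are reported
    through the ITS graph attributes, not here; see
    :func:`enumerate_completions` which consumes both.
    """
    return [
        HydrogenDelta(n, d["hcount"][1] - d["hcount"][0])
        for n, d in sorted(its.nodes(data=True))
        if d["hcount"][1] != d["hcount"][0]
    ]


def _tokens(its: nx.Graph):
    """Donor and acceptor hydrogen tokens.

    A token is one transferable hydrogen: ``("site", vertex)`` for an
    implicit hydrogen on a mapped atom, ``("free", side, comp, i)`` for a
    hydrogen of an unmapped all-H molecule.  Free tokens of one component
    are bonded to each other on their side.
    """
    donors: list[tuple] = []
    acceptors: list[tuple] = []
    for hd in hydrogen_deltas(its):
        if hd.delta < 0:
            donors.extend(("site", hd.vertex) for _ in range(-hd.delta))
        else:
            acceptors.extend(("site", hd.vertex) for _ in range(hd.delta))
    for ci, size in enumerate(its.graph.get("free_h_reactant", ())):
        if size > 2:
            raise ValueError(f"unsupported all-hydrogen molecule of {size} atoms")
        donors.extend(("free", 0, ci, i) for i in range(size))
    for ci, size in enumerate(its.graph.get("free_h_product", ())):
        if size > 2:
            raise ValueError(f"unsupported all-hydrogen molecule of {size} atoms")
        acceptors.extend(("free", 1, ci, i) for i in range(size))
    return donors, acceptors


def _materialize(its: nx.Graph, pairing: list[tuple[tuple, tuple]]) -> nx.Graph:
    """Build a candidate completed ITS for one donor->acceptor pairing."""
    out = nx.Graph(free_h_reactant=(), free_h_product=())
    for n, d in its.nodes(data=True):
        out.add_node(n, **dict(d))
    for u, v, d in its.edges(data=True):
        out.add_edge(u, v, **dict(d))
    next_id = (max(out.nodes) + 1) if out.number_of_nodes() else 0
    vertex_of_token: dict[tuple, int] = {}
    for donor, acceptor in pairing:
        hv = next_id
        next_id += 1
        out.add_node(
            hv, element="H", charge=(0, 0), hcount=(0, 0), aromatic=(False, False)
        )
        vertex_of_token[donor] = hv
        vertex_of_token[acceptor] = hv
        if donor[0] == "site":
            site = donor[1]
            hg, hh = out.nodes[site]["hcount"]
            out.nodes[site]["hcount"] = (hg - 1, hh)
            out.add_edge(hv, site, order=(1, 0))
        if acceptor[0] == "site":
            site = acceptor[1]
            hg, hh = out.nodes[site]["hcount"]
            out.nodes[site]["hcount"] = (hg, hh - 1)
            if out.has_edge(hv, site):
                out.edges[hv, site]["order"] = (1, 1)
            else:
                out.add_edge(hv, site, order=(0, 1))
    # bond free-component partners on their own side
    for side, attr in ((0, "free_h_reactant"), (1, "free_h_product")):
        for ci, size in enumerate(its.graph.get(attr, ())):
            if size == 2:
                a = vertex_of_token[("free", side, ci, 0)]
                b = vertex_of_token[("free", side, ci, 1)]
                order = (1, 0) if side == 0 else (0, 1)
                if a != b:
                    out.add_edge(a, b, order=order)
    return out


def enumerate_completions(its: nx.Graph, cap: int = DEFAULT_CAP) -> CompletionResult:
    """Enumerate hydrogen completions of an ITS and classify the outcome.

    All bijections between donor hydrogens and acceptor hydrogens are tried
    (their count is the factorial of the number of transferred hydrogens);
    candidates are deduplicated by ITS isomorphism.  ``unique`` means every
    pairing gives the same reaction mechanism; otherwise all non-isomorphic
    candidates are returned as ``ambiguous``.
    """
    if cap < 1:
        raise ValueError("cap must be at least 1")
    donors, acceptors = _tokens(its)
    if len(donors) != len(acceptors):
        return CompletionResult("unbalanced", [], 0)
    t = len(donors)
    if t == 0:
        return CompletionResult("unique", [its], 1)
    n_pairings = math.factorial(t)
    if n_pairings > cap:
        return CompletionResult("overflow", [], n_pairings)

    buckets: dict[str, list[nx.Graph]] = {}
    for perm in permutations(acceptors):
        candidate = _materialize(its, list(zip(donors, perm)))
        key = canonical_key(candidate)
        for rep in buckets.setdefault(key, []):
            if its_isomorphic(candidate, rep):
                break
        else:
            buckets[key].append(candidate)
    distinct = [g for reps in buckets.values() for g in reps]
    status = "unique" if len(distinct) == 1 else "ambiguous"
    return CompletionResult(status, distinct, n_pairings)
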