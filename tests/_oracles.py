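"""Independent brute-force oracles used to validate the fast paths.

These deliberately avoid the library's own algorithms: isomorphism is
decided by exhaustive label-guided assignment, and minimum cycle bases by
greedy GF(2) elimination over all simple cycles sorted by length.
"""

from __future__ import annotations

import random

import networkx as nx


def brute_force_isomorphic(a: nx.Graph, b: nx.Graph, node_match, edge_match) -> bool:
    """Exhaustive search for a label-preserving isomorphism."""
    if a.number_of_nodes() != b.number_of_nodes():
        return False
    if a.number_of_edges() != b.number_of_edges():
        return False
    na = list(a.nodes)
    nb = list(b.nodes)

    def backtrack(i: int, assigned: dict, used: set) -> bool:
        if i == len(na):
            return True
        u = na[i]
        for v in nb:
            if v in used or not node_match(a.nodes[u], b.nodes[v]):
                continue
            ok = True
            for w, img in assigned.items():
                ea = a.has_edge(u, w)
                eb = b.has_edge(v, img)
                if ea != eb or (ea and not edge_match(a.edges[u, w], b.edges[v, img])):
                    ok = False
                    break
            if ok:
                assigned[u] = v
                used.add(v)
                if backtrack(i + 1, assigned, used):
                    return True
                del assigned[u]
                used.remove(v)
        return False

    return backtrack(0, {}, set())


def mcb_descriptor_oracle(g: nx.Graph) -> list[int]:
    """Cycle descriptor via greedy minimum-weight GF(2) cycle-space basis."""
    desc: list[int] = []
    for comp_nodes in nx.connected_components(g):
        comp = g.subgraph(comp_nodes)
        dim = comp.number_of_edges() - comp.number_of_nodes() + 1
        if dim == 0:
            desc.append(0)
            continue
        eidx = {frozenset(e): i for i, e in enumerate(comp.edges())}
        cycles = sorted(nx.simple_cycles(comp), key=len)
        basis: dict[int, int] = {}
        lengths: list[int] = []
        for cyc in cycles:
            vec = 0
            for i in range(len(cyc)):
                vec ^= 1 << eidx[frozenset((cyc[i], cyc[(i + 1) % len(cyc)]))]
            while vec:
                lead = vec.bit_length() - 1
                if lead in basis:
                    vec ^= basis[lead]
                else:
                    basis[lead] = vec
                    lengths.append(len(cyc))
                    break
            if len(lengths) == dim:
                break
        desc.extend(lengths)
    return sorted(desc)


_ELEMENTS = ("C", "N", "O", "H")
_ORDERS = (0, 1, 2)


def random_its_like_graph(rng: random.Random, n: int) -> nx.Graph:
    """Random connected labeled graph shaped like an ITS (pair attributes)."""
    g = nx.Graph(free_h_reactant=(), free_h_product=())
    for i in range(n):
        g.add_node(
            i,
            element=rng.choice(_ELEMENTS),
            charge=(rng.choice((0, 0, 0, 1, -1)),) * 2,
            hcount=(rng.randint(0, 3), rng.randint(0, 3)),
            aromatic=(False, False),
        )
    nodes = list(range(n))
    rng.shuffle(nodes)
    for i in range(1, n):  # random spanning tree keeps it connected
        u = nodes[i]
        v = nodes[rng.randrange(i)]
        g.add_edge(u, v, order=_random_order(rng))
    for _ in range(rng.randint(0, n // 2)):
        u, v = rng.sample(range(n), 2)
        if not g.has_edge(u, v):
            g.add_edge(u, v, order=_random_order(rng))
    return g


def _random_order(rng: random.Random) -> tuple[int, int]:
    while True:
        pair = (rng.choice(_ORDERS), rng.choice(_ORDERS))
        if pair != (0, 0):
            return pair


def permuted_copy(g: nx.Graph, rng: random.Random) -> nx.Graph:
    nodes = list(g.nodes)
    target = list(nodes)
    rng.shuffle(target)
    return nx.relabel_nodes(g, dict(zip(nodes, target)), copy=True)


def random_sparse_graph(rng: random.Random, n: int, extra_edges: int) -> nx.Graph:
    """Random unlabeled graph: spanning structure plus a few chords."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(1, n):
        g.add_edge(i, rng.randrange(i))
    for _ in range(extra_edges):
        u, v = rng.sample(range(n), 2)
        g.add_edge(u, v)
    return g
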