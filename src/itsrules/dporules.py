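"""Double-pushout (DPO) rewriting rules derived from ITS templates.

A template (partial ITS) is equivalent to a DPO span L <- K -> R: L is its
reactant-side projection, R its product-side projection, and K the common
context — all vertices plus the edges whose bond order is unchanged.  Rules
are serialized to MØD-style GML, applied to substrate molecules by
label-preserving subgraph monomorphism (explicit-hydrogen lifting on
demand, standard valence guard on the result), and scored by coverage (the
fraction of recorded reactions whose products the rule regenerates) and
novelty (the fraction of successful applications producing a reaction not
in the record).  Reversing a rule just swaps L and R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
from networkx.algorithms import isomorphism as nxiso

from .its_core import Template, changed_edges

logger = logging.getLogger(__name__)

_BOND_LABEL = {1: "-", 2: "=", 3: "#"}
_LABEL_BOND = {v: k for k, v in _BOND_LABEL.items()}

#: maximum total valence per element; adjusted by formal charge for N/O/S/P
DEFAULT_VALENCE = {
    "H": 1, "C": 4, "N": 3, "O": 2, "F": 1, "Cl": 1, "Br": 1, "I": 1,
    "S": 6, "P": 5, "B": 3, "Si": 4,
}


class RuleError(ValueError):
    pass


@dataclass
class DPORule:
    """Span L <- K -> R over a shared vertex set.

    ``left``/``right``/``context`` are graphs on identical node ids (the
    embeddings l and r are the identity on ids); context edges carry the
    bond order shared by both sides.  ``center_nodes`` marks the reaction
    center for match accounting.
    """

    left: nx.Graph
    context: nx.Graph
    right: nx.Graph
    radius: int = 0
    rule_id: str = "rule"
    center_nodes: frozenset = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# template -> rule


def _projection(graph: nx.Graph, side: int) -> nx.Graph:
    out = nx.Graph()
    for n, d in graph.nodes(data=True):
        out.add_node(
            n,
            element=d["element"],
            charge=d["charge"][side],
            hcount=d["hcount"][side],
        )
    for u, v, d in graph.edges(data=True):
        if d["order"][side]:
            out.add_edge(u, v, order=d["order"][side])
    return out


def template_to_rule(t: Template, rule_id: str = "rule") -> DPORule:
    """Project a template onto its DPO span.

    L and R are the two side projections; K keeps every vertex and exactly
    the edges present with equal order on both sides.  Refused for templates
    without any change (nothing to rewrite).
    """
    g = t.graph
    for u, v, d in g.edges(data=True):
        if d["order"] == (0, 0):
            raise RuleError(f"edge ({u},{v}) absent on both sides")
    changed = changed_edges(g)
    label_changed = any(
        d["charge"][0] != d["charge"][1] or d["hcount"][0] != d["hcount"][1]
        for _, d in g.nodes(data=True)
    )
    if not changed and not label_changed:
        raise RuleError("template encodes no change; refusing to build a rule")
    left = _projection(g, 0)
    right = _projection(g, 1)
    context = nx.Graph()
    for n, d in g.nodes(data=True):
        context.add_node(n, element=d["element"])
    for u, v, d in g.edges(data=True):
        if d["order"][0] == d["order"][1]:
            context.add_edge(u, v, order=d["order"][0])
    return DPORule(
        left=left,
        context=context,
        right=right,
        radius=t.radius,
        rule_id=rule_id,
        center_nodes=t.center_nodes & set(g.nodes),
    )


def strip_hydrogens(t: Template) -> Template:
    """Raw-template variant: drop explicit hydrogens and hydrogen counts.

    Mirrors templates extracted without hydrogen completion; rules built
    from them ignore hydrogen movement and are deliberately deficient for
    mechanisms that transfer hydrogens.
    """
    g = nx.Graph(**t.graph.graph)
    for n, d in t.graph.nodes(data=True):
        if d["element"] == "H":
            continue
        d = dict(d)
        d["hcount"] = (d["hcount"][0], d["hcount"][0])
        g.add_node(n, **d)
    for u, v, d in t.graph.edges(data=True):
        if u in g and v in g:
            g.add_edge(u, v, **dict(d))
    return Template(graph=g, radius=t.radius, center_nodes=t.center_nodes & set(g.nodes))


def invert_rule(rule: DPORule) -> DPORule:
    """Swap L and R; double inversion is the identity."""
    return replace(rule, left=rule.right, right=rule.left)


# ---------------------------------------------------------------------------
# GML serialization

_CANON_BRANCH_CAP = 20000


def _render_atom(element: str, charge: int) -> str:
    if charge == 0:
        return element
    sign = "+" if charge > 0 else "-"
    mag = abs(charge)
    return element + sign * mag


def _parse_atom(label: str) -> tuple[str, int]:
    element = label.rstrip("+-")
    tail = label[len(element):]
    charge = tail.count("+") - tail.count("-")
    return element, charge


def _rule_union_labels(rule: DPORule):
    """Serialization-relevant node and edge labels of a rule."""
    nlabel = {}
    for n in rule.context.nodes:
        nlabel[n] = (
            _render_atom(rule.left.nodes[n]["element"], rule.left.nodes[n].get("charge", 0)),
            _render_atom(rule.right.nodes[n]["element"], rule.right.nodes[n].get("charge", 0)),
        )
    elabel = {}
    edges = set(rule.left.edges) | set(rule.right.edges)
    for u, v in edges:
        key = frozenset((u, v))
        ol = rule.left.edges[u, v]["order"] if rule.left.has_edge(u, v) else 0
        orr = rule.right.edges[u, v]["order"] if rule.right.has_edge(u, v) else 0
        elabel[key] = (ol, orr)
    return nlabel, elabel


def _canonical_order(nodes, adj, nlabel, elabel) -> list:
    """Canonical vertex order: WL-style refinement, then lexicographically
    minimal placement over tied orbits (exhaustive with a branch cap)."""
    lab = {n: str(nlabel[n]) for n in nodes}
    for _ in range(len(nodes)):
        new = {
            n: lab[n]
            + "|"
            + ",".join(sorted(f"{elabel[frozenset((n, m))]}{lab[m]}" for m in adj[n]))
            for n in nodes
        }
        if len(set(new.values())) == len(set(lab.values())):
            lab = new
            break
        lab = new

    best: list | None = None
    budget = [_CANON_BRANCH_CAP]

    def signature(order: list) -> tuple:
        idx = {n: i for i, n in enumerate(order)}
        placed_edges = sorted(
            (min(idx[u], idx[v]), max(idx[u], idx[v]), str(elabel[frozenset((u, v))]))
            for u in order
            for v in adj[u]
            if v in idx and idx[v] < idx[u]
        )
        return (tuple(lab[n] for n in order), tuple(placed_edges))

    def extend(order: list, remaining: set) -> None:
        nonlocal best
        if budget[0] <= 0:
            return
        if not remaining:
            sig = signature(order)
            if best is None or sig < signature(best):
                best = list(order)
            budget[0] -= 1
            return
        idx = {n: i for i, n in enumerate(order)}

        def cand_key(n):
            back = sorted(
                (idx[m], str(elabel[frozenset((n, m))])) for m in adj[n] if m in idx
            )
            return (lab[n], tuple(back))

        lo = min(cand_key(n) for n in remaining)
        for n in sorted(remaining, key=lambda n: str(n)):
            if cand_key(n) == lo:
                order.append(n)
                extend(order, remaining - {n})
                order.pop()
                budget[0] -= 1

    extend([], set(nodes))
    if best is None:  # pragma: no cover - cap exhausted, deterministic fallback
        best = sorted(nodes, key=lambda n: (lab[n], str(n)))
    return best


def rule_to_gml(rule: DPORule) -> str:
    """Serialize a rule to MØD-style GML.

    Unchanged vertices and edges go to ``context``; anything whose label or
    order differs between the sides goes to ``left``/``right``.  Node ids
    follow a canonical order, so isomorphic rules serialize to identical
    text.
    """
    nlabel, elabel = _rule_union_labels(rule)
    adj = {n: set() for n in rule.context.nodes}
    for key in elabel:
        u, v = tuple(key)
        adj[u].add(v)
        adj[v].add(u)
    order = _canonical_order(list(rule.context.nodes), adj, nlabel, elabel)
    idx = {n: i + 1 for i, n in enumerate(order)}

    left_lines, ctx_lines, right_lines = [], [], []
    for n in order:
        ll, rl = nlabel[n]
        if ll == rl:
            ctx_lines.append(f'      node [ id {idx[n]} label "{ll}" ]')
        else:
            left_lines.append(f'      node [ id {idx[n]} label "{ll}" ]')
            right_lines.append(f'      node [ id {idx[n]} label "{rl}" ]')
    sorted_edges = sorted(
        elabel.items(), key=lambda kv: tuple(sorted(idx[n] for n in kv[0]))
    )
    for key, (ol, orr) in sorted_edges:
        a, b = sorted(idx[n] for n in key)
        if ol == orr:
            ctx_lines.append(
                f'      edge [ source {a} target {b} label "{_BOND_LABEL[ol]}" ]'
            )
        else:
            if ol:
                left_lines.append(
                    f'      edge [ source {a} target {b} label "{_BOND_LABEL[ol]}" ]'
                )
            if orr:
                right_lines.append(
                    f'      edge [ source {a} target {b} label "{_BOND_LABEL[orr]}" ]'
                )
    parts = [
        "rule [",
        f'   ruleID "{rule.rule_id}"',
        "   left [",
        *left_lines,
        "   ]",
        "   context [",
        *ctx_lines,
        "   ]",
        "   right [",
        *right_lines,
        "   ]",
        "]",
    ]
    return "\n".join(parts) + "\n"


def _tokenize_gml(text: str):
    import re

    return re.findall(r'\[|\]|"[^"]*"|\S+', text)


def parse_gml(text: str) -> DPORule:
    """Read a rule back from GML (inverse of :func:`rule_to_gml` up to rule
    isomorphism; hydrogen counts are not part of the GML dialect)."""
    tokens = _tokenize_gml(text)

    def parse_block(i):
        obj: dict = {}
        assert tokens[i] == "["
        i += 1
        while tokens[i] != "]":
            key = tokens[i]
            if tokens[i + 1] == "[":
                sub, i = parse_block(i + 1)
                obj.setdefault(key, []).append(sub)
            else:
                val = tokens[i + 1].strip('"')
                obj[key] = val
                i += 2
        return obj, i + 1

    if tokens[0] != "rule":
        raise RuleError("not a rule GML document")
    doc, _ = parse_block(1)
    rule_id = doc.get("ruleID", "rule")

    def section(name):
        blocks = doc.get(name, [{}])
        return blocks[0] if blocks else {}

    left_s, ctx_s, right_s = section("left"), section("context"), section("right")
    left, context, right = nx.Graph(), nx.Graph(), nx.Graph()

    def add_nodes(sec, *graphs):
        for nd in sec.get("node", []):
            el, ch = _parse_atom(nd["label"])
            for g in graphs:
                g.add_node(int(nd["id"]), element=el, charge=ch, hcount=0)

    add_nodes(ctx_s, left, right)
    add_nodes(left_s, left)
    add_nodes(right_s, right)
    for n, d in left.nodes(data=True):
        context.add_node(n, element=d["element"])
    for n, d in right.nodes(data=True):
        if n not in context:
            context.add_node(n, element=d["element"])

    def add_edges(sec, *graphs):
        for ed in sec.get("edge", []):
            order = _LABEL_BOND[ed["label"]]
            for g in graphs:
                g.add_edge(int(ed["source"]), int(ed["target"]), order=order)

    add_edges(ctx_s, left, right, context)
    add_edges(left_s, left)
    add_edges(right_s, right)
    return DPORule(left=left, context=context, right=right, rule_id=rule_id)


def rule_isomorphic(a: DPORule, b: DPORule) -> bool:
    """Isomorphism of rules over their serialized content (element, charge,
    and side-wise bond orders; hydrogen counts excluded, matching GML)."""
    na, ea = _rule_union_labels(a)
    nb, eb = _rule_union_labels(b)

    def union_graph(rule, nlabel, elabel):
        g = nx.Graph()
        for n in rule.context.nodes:
            g.add_node(n, lbl=nlabel[n])
        for key, lbl in elabel.items():
            u, v = tuple(key)
            g.add_edge(u, v, lbl=lbl)
        return g

    return nx.is_isomorphic(
        union_graph(a, na, ea),
        union_graph(b, nb, eb),
        node_match=lambda x, y: x["lbl"] == y["lbl"],
        edge_match=lambda x, y: x["lbl"] == y["lbl"],
    )


# ---------------------------------------------------------------------------
# application


def lift_hydrogens(g: nx.Graph) -> nx.Graph:
    """Materialize every implicit hydrogen as an explicit vertex."""
    out = nx.Graph()
    nid = 0
    remap = {}
    for n, d in g.nodes(data=True):
        remap[n] = nid
        out.add_node(nid, element=d["element"], charge=d.get("charge", 0), hcount=0)
        nid += 1
    for u, v, d in g.edges(data=True):
        out.add_edge(remap[u], remap[v], order=d["order"])
    for n, d in g.nodes(data=True):
        for _ in range(d.get("hcount", 0)):
            out.add_node(nid, element="H", charge=0, hcount=0)
            out.add_edge(remap[n], nid, order=1)
            nid += 1
    return out


def fold_hydrogens(g: nx.Graph) -> nx.Graph:
    """Fold degree-1 hydrogens on heavy atoms back into hydrogen counts."""
    out = nx.Graph()
    folded = set()
    for n, d in g.nodes(data=True):
        if d["element"] == "H" and d.get("charge", 0) == 0 and g.degree(n) == 1:
            (m,) = g.neighbors(n)
            if g.nodes[m]["element"] != "H" and g.edges[n, m]["order"] == 1:
                folded.add(n)
    for n, d in g.nodes(data=True):
        if n in folded:
            continue
        extra = sum(1 for m in g.neighbors(n) if m in folded)
        out.add_node(
            n,
            element=d["element"],
            charge=d.get("charge", 0),
            hcount=d.get("hcount", 0) + extra,
            map=0,
            aromatic=d.get("aromatic", False),
        )
    for u, v, d in g.edges(data=True):
        if u not in folded and v not in folded:
            out.add_edge(u, v, order=d["order"])
    return out


def _max_valence(element: str, charge: int, table: dict[str, int]) -> int:
    base = table.get(element)
    if base is None:
        return 8
    if element in ("N", "O", "S", "P") and charge > 0:
        return base + charge
    if charge < 0:
        return max(base + charge, 0)
    return base


def _valence_ok(g: nx.Graph, nodes, table: dict[str, int]) -> bool:
    for n in nodes:
        d = g.nodes[n]
        total = sum(ed["order"] for _, _, ed in g.edges(n, data=True))
        total += d.get("hcount", 0)
        if total > _max_valence(d["element"], d.get("charge", 0), table):
            logger.debug("valence guard: %s%+d exceeds maximum", d["element"], d.get("charge", 0))
            return False
    return True


def canonical_molecule_key(g: nx.Graph) -> tuple[str, ...]:
    """Canonical SMILES multiset of a molecular graph's components."""
    from rdkit import Chem

    from .chemio import _graph_to_mol

    keys = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        mol = _graph_to_mol(sub, {})
        keys.append(Chem.MolToSmiles(mol, canonical=True))
    return tuple(sorted(keys))


def _match_node(host: dict, pattern: dict) -> bool:
    return host["element"] == pattern["element"] and host.get("charge", 0) == pattern.get("charge", 0)


def _match_edge(host: dict, pattern: dict) -> bool:
    return host["order"] == pattern["order"]


def _monomorphisms(host: nx.Graph, pattern: nx.Graph):
    gm = nxiso.GraphMatcher(host, pattern, node_match=_match_node, edge_match=_match_edge)
    for m in gm.subgraph_monomorphisms_iter():
        yield {pn: hn for hn, pn in m.items()}


def _rewrite(host: nx.Graph, rule: DPORule, match: dict) -> nx.Graph:
    out = host.copy()
    for u, v in rule.left.edges:
        if not rule.context.has_edge(u, v):
            out.remove_edge(match[u], match[v])
    for u, v, d in rule.right.edges(data=True):
        if not rule.context.has_edge(u, v):
            out.add_edge(match[u], match[v], order=d["order"])
    for n, d in rule.right.nodes(data=True):
        out.nodes[match[n]]["charge"] = d.get("charge", 0)
    return out


def apply_rule(
    rule: DPORule,
    substrate: nx.Graph,
    valence_table: dict[str, int] | None = None,
) -> set[tuple[str, ...]]:
    """Apply a rule to a substrate (one graph, components = molecules).

    Enumerates label-preserving monomorphisms of L (implicit hydrogens are
    lifted to explicit vertices first so pattern hydrogens can bind),
    rewrites each match, folds hydrogens back, and returns the product
    multisets as canonical-SMILES tuples.  Matches whose rewrite pushes an
    atom over its maximum valence are discarded.
    """
    table = valence_table or DEFAULT_VALENCE
    host = lift_hydrogens(substrate)
    products: set[tuple[str, ...]] = set()
    for match in _monomorphisms(host, rule.left):
        rewritten = _rewrite(host, rule, match)
        if not _valence_ok(rewritten, [match[n] for n in rule.left.nodes], table):
            continue
        products.add(canonical_molecule_key(fold_hydrogens(rewritten)))
    return products


def count_matches(rule: DPORule, substrate: nx.Graph) -> int:
    """Number of distinct reaction-center placements of L in the substrate.

    Counting placements of the embedded center (rather than raw
    monomorphisms) makes the count monotone non-increasing in the template
    radius: any center placement extendable at radius r+1 extends at r.
    """
    host = lift_hydrogens(substrate)
    anchors = sorted(rule.center_nodes) or sorted(rule.left.nodes)
    placements = {
        tuple(m[n] for n in anchors) for m in _monomorphisms(host, rule.left)
    }
    return len(placements)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class RuleMetrics:
    direction: str
    coverage: float
    novelty: float
    attempted: int
    recovered: int
    successful: int
    novel: int


def reaction_sides(rxn, direction: str = "forward") -> tuple[nx.Graph, nx.Graph]:
    """Substrate and expected-product graphs of a mapped reaction, with
    explicit hydrogens folded into counts."""
    sub, prod = rxn.reactants, rxn.products
    if direction == "backward":
        sub, prod = prod, sub
    return fold_hydrogens(sub), fold_hydrogens(prod)


def evaluate_rules(
    rules: list[DPORule],
    reactions: list,
    direction: str = "forward",
    rule_map: dict | None = None,
    valence_table: dict[str, int] | None = None,
    extra_substrates: list[nx.Graph] = (),
) -> RuleMetrics:
    """Coverage and novelty of a rule set against recorded reactions.

    Forward: rules applied to reactant multisets must regenerate the
    recorded products; backward: inverted rules on products must regenerate
    the reactants.  ``rule_map`` (reaction index -> rule_id) restricts each
    reaction to its own extracted rule; without it every rule is tried.
    Novelty counts successful (substrate, product) outcomes whose pair is
    not isomorphic to any recorded reaction; ``extra_substrates`` are
    additional molecule multisets that feed the novelty tally (all rules
    tried) without entering the coverage denominator.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    if not reactions:
        raise ValueError("empty reaction list")
    applied = [invert_rule(r) for r in rules] if direction == "backward" else rules
    by_id = {r.rule_id: r for r in applied}

    recorded: set[tuple] = set()
    cases = []
    for i, rxn in enumerate(reactions):
        sub, prod = reaction_sides(rxn, direction)
        sub_key = canonical_molecule_key(sub)
        prod_key = canonical_molecule_key(prod)
        recorded.add((sub_key, prod_key))
        cases.append((i, sub, sub_key, prod_key))

    recovered = successful = novel = 0
    for i, sub, sub_key, prod_key in cases:
        if rule_map is not None and i in rule_map:
            todo = [by_id[rule_map[i]]]
        else:
            todo = applied
        outputs: set[tuple[str, ...]] = set()
        for rule in todo:
            outputs |= apply_rule(rule, sub, valence_table)
        if prod_key in outputs:
            recovered += 1
        for out in outputs:
            successful += 1
            if (sub_key, out) not in recorded:
                novel += 1
    for sub in extra_substrates:
        sub_key = canonical_molecule_key(sub)
        outputs = set()
        for rule in applied:
            outputs |= apply_rule(rule, sub, valence_table)
        for out in outputs:
            successful += 1
            if (sub_key, out) not in recorded:
                novel += 1
    attempted = len(reactions)
    return RuleMetrics(
        direction=direction,
        coverage=recovered / attempted,
        novelty=novel / successful if successful else 0.0,
        attempted=attempted,
        recovered=recovered,
        successful=successful,
        novel=novel,
    )


# ---------------------------------------------------------------------------
# hierarchical application


def _chain_templates(node_template: Template, depth: int) -> list[Template]:
    """Aligned templates Q_0..Q_depth rebuilt inside one representative's
    template graph (BFS from the embedded center; node ids shared)."""
    g = node_template.graph
    center = set(node_template.center_nodes)
    chain = []
    nodes = set(center)
    frontier = set(center)
    for r in range(depth + 1):
        if r > 0:
            frontier = {m for n in frontier for m in g.neighbors(n)} - nodes
            nodes |= frontier
        sub = nx.Graph(**g.graph)
        for n in nodes:
            sub.add_node(n, **g.nodes[n])
        if r == 0:
            for u, v, d in g.edges(data=True):
                if u in center and v in center and d["order"][0] != d["order"][1]:
                    sub.add_edge(u, v, **d)
        else:
            for u, v, d in g.subgraph(nodes).edges(data=True):
                sub.add_edge(u, v, **d)
        chain.append(Template(graph=sub, radius=r, center_nodes=frozenset(center)))
    return chain


def _extend_embedding(host: nx.Graph, small: nx.Graph, big: nx.Graph, f: dict) -> list[dict]:
    """All extensions of a monomorphism of ``small`` to its supergraph ``big``."""
    new_nodes = [n for n in big.nodes if n not in small]
    results: list[dict] = []

    def backtrack(i: int, cur: dict, used: set) -> None:
        if i == len(new_nodes):
            results.append(dict(cur))
            return
        u = new_nodes[i]
        du = big.nodes[u]
        mapped_nbrs = [v for v in big.neighbors(u) if v in cur]
        if mapped_nbrs:
            cand = set(host.neighbors(cur[mapped_nbrs[0]]))
        else:  # pragma: no cover - context growth is always edge-connected
            cand = set(host.nodes)
        for w in cand:
            if w in used:
                continue
            if not _match_node(host.nodes[w], du):
                continue
            ok = all(
                host.has_edge(w, cur[v])
                and _match_edge(host.edges[w, cur[v]], big.edges[u, v])
                for v in mapped_nbrs
            )
            if ok:
                cur[u] = w
                backtrack(i + 1, cur, used | {w})
                del cur[u]

    backtrack(0, dict(f), set(f.values()))
    return results


def hierarchical_apply(
    hierarchy, substrate: nx.Graph, depth: int,
    valence_table: dict[str, int] | None = None,
) -> tuple[set[tuple[str, ...]], int]:
    """Apply all depth-level rules of a template hierarchy via the hierarchy.

    The radius-0 pattern of each top-level class is matched from scratch
    (one match attempt per class); embeddings are then only *extended* along
    each descendant's nested template chain, never re-searched, so the
    product set equals flat application of every depth-level rule while the
    number of from-scratch match attempts is at most the flat count.
    Returns ``(product_sets, match_attempts)``.
    """
    levels = hierarchy.levels()
    if depth >= len(levels) or not levels[depth]:
        raise ValueError(f"hierarchy not built to depth {depth}")
    table = valence_table or DEFAULT_VALENCE
    host = lift_hydrogens(substrate)
    products: set[tuple[str, ...]] = set()
    attempts = 0

    for top in levels[0]:
        # gather depth-level descendants of this radius-0 class
        nodes = [top]
        for _ in range(depth):
            nodes = [hierarchy.nodes[c] for n in nodes for c in n.children]
        if not nodes:
            continue
        attempts += 1
        rule0 = template_to_rule(Template(
            graph=top.template.graph, radius=0,
            center_nodes=top.template.center_nodes,
        ))
        base = list(_monomorphisms(host, rule0.left))
        if not base:
            continue
        for node in nodes:
            chain = _chain_templates(node.template, depth)
            rules = [template_to_rule(t, rule_id=f"n{node.node_id}_r{t.radius}") for t in chain]
            # align this node's own Q_0 pattern with the class pattern
            gm = nxiso.GraphMatcher(
                rules[0].left, rule0.left,
                node_match=_match_node, edge_match=_match_edge,
            )
            if not gm.is_isomorphic():
                continue
            sigma = gm.mapping  # node of rules[0].left -> node of rule0.left
            embeddings = [{n: f[sigma[n]] for n in rules[0].left.nodes} for f in base]
            for r in range(1, depth + 1):
                embeddings = [
                    g
                    for f in embeddings
                    for g in _extend_embedding(host, rules[r - 1].left, rules[r].left, f)
                ]
                if not embeddings:
                    break
            final_rule = rules[depth]
            for f in embeddings:
                rewritten = _rewrite(host, final_rule, f)
                if _valence_ok(rewritten, [f[n] for n in final_rule.left.nodes], table):
                    products.add(canonical_molecule_key(fold_hydrogens(rewritten)))
    return products, attempts
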