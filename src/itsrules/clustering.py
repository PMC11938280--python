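"""Flat and hierarchical clustering of reaction templates.

Reactions are grouped by isomorphism of their (extended) reaction centers:
two reactions belong to one cluster exactly when their radius-r templates
are isomorphic as labeled ITS graphs.  The flat procedure iterates over the
input, matching each template against cluster representatives (first match
wins, first-seen member is the representative).  The hierarchy indexes
templates by radius: depth d of the rooted tree partitions the reactions by
isomorphism of their radius-(d-1) templates, so each level refines its
parent and matching can be confined to the children of the already-matched
node — far fewer isomorphism calls than flat clustering at the deepest
radius.

Canonical-key buckets (``prefilter=True``, the default) skip provably
non-isomorphic candidates; they are purely an optimization and never change
the partition.  Pass ``prefilter=False`` to count raw isomorphism calls,
e.g. when comparing the hierarchical and flat strategies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .aam_consensus import its_isomorphic
from .chemio import canonical_key
from .its_core import Template, extend_center, reaction_center

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    representative: Template
    members: list = field(default_factory=list)


@dataclass
class ClusterPartition:
    clusters: list[Cluster] = field(default_factory=list)

    def partition(self) -> list[set]:
        return [set(c.members) for c in self.clusters]


class _Matcher:
    """First-match lookup with optional canonical-key bucket prefilter."""

    def __init__(self, prefilter: bool):
        self.prefilter = prefilter
        self.items: list = []
        self.buckets: dict[str, list] = {}

    def find(self, graph: nx.Graph, key: str, graph_of) -> object | None:
        candidates = self.buckets.get(key, []) if self.prefilter else self.items
        for item in candidates:
            if its_isomorphic(graph_of(item), graph):
                return item
        return None

    def add(self, item, key: str) -> None:
        self.items.append(item)
        self.buckets.setdefault(key, []).append(item)


def flat_cluster(
    templates: list[tuple[object, Template]], prefilter: bool = True
) -> ClusterPartition:
    """Partition ``(reaction_id, template)`` pairs by template isomorphism.

    All templates must share one radius.  Clusters are ordered by first
    appearance; the representative is the first-seen template.
    """
    radii = {t.radius for _, t in templates}
    if len(radii) > 1:
        raise ValueError(f"templates mix radii {sorted(radii)}")
    part = ClusterPartition()
    matcher = _Matcher(prefilter)
    for rid, tpl in templates:
        key = canonical_key(tpl.graph)
        cluster = matcher.find(tpl.graph, key, lambda c: c.representative.graph)
        if cluster is None:
            cluster = Cluster(representative=tpl)
            part.clusters.append(cluster)
            matcher.add(cluster, key)
        cluster.members.append(rid)
    return part


# ---------------------------------------------------------------------------
# hierarchy


@dataclass
class HierarchyNode:
    """Tree node holding the representative radius-(depth-1) template."""

    node_id: int
    template: Template | None  # None only for the formal root
    depth: int  # root = 0; depth d >= 1 holds radius d-1 templates
    parent: int | None
    children: list[int] = field(default_factory=list)
    members: list = field(default_factory=list)
    saturated: bool = False  # template identical to the parent's (Q_r = Q_{r-1})


@dataclass
class TemplateHierarchy:
    max_radius: int
    nodes: dict[int, HierarchyNode] = field(default_factory=dict)
    root_id: int = 0

    def __post_init__(self) -> None:
        if not self.nodes:
            self.nodes[0] = HierarchyNode(0, None, 0, None)

    @property
    def root(self) -> HierarchyNode:
        return self.nodes[self.root_id]

    def new_node(self, template: Template, parent: HierarchyNode, saturated: bool) -> HierarchyNode:
        nid = max(self.nodes) + 1
        node = HierarchyNode(nid, template, parent.depth + 1, parent.node_id, saturated=saturated)
        self.nodes[nid] = node
        parent.children.append(nid)
        return node

    def levels(self) -> list[list[HierarchyNode]]:
        """Nodes grouped by depth, root excluded."""
        out: list[list[HierarchyNode]] = [[] for _ in range(self.max_radius + 1)]
        for node in self.nodes.values():
            if node.depth >= 1:
                out[node.depth - 1].append(node)
        return out

    def partition_at_depth(self, depth: int) -> list[set]:
        return [set(n.members) for n in self.levels()[depth - 1]]


def build_hierarchy(
    reactions: list[tuple[object, nx.Graph]],
    max_radius: int,
    prefilter: bool = True,
) -> TemplateHierarchy:
    """Insert reactions into the radius-indexed template hierarchy.

    For each reaction the templates Q_0, Q_1, ... are matched against the
    children of the current node; the first radius with no isomorphic child
    starts a fresh chain of nodes down to ``max_radius``.  A template that
    saturates (Q_r identical to Q_{r-1}, the full ITS reached) is carried
    down without further isomorphism checks, so depth-d partitions remain
    defined at every depth.  Reactions with an empty reaction center carry
    no mechanism and are skipped with a warning.
    """
    if max_radius < 0:
        raise ValueError("max_radius must be non-negative")
    h = TemplateHierarchy(max_radius=max_radius)
    matchers: dict[int, _Matcher] = {}
    for rid, its in reactions:
        center = reaction_center(its)
        if center.number_of_nodes() == 0:
            logger.warning("reaction %r has an empty reaction center; skipped", rid)
            continue
        node = h.root
        prev_tpl: Template | None = None
        for r in range(max_radius + 1):
            tpl = extend_center(its, center, r)
            saturated = (
                prev_tpl is not None
                and tpl.graph.number_of_nodes() == prev_tpl.graph.number_of_nodes()
            )
            child = None
            if saturated:
                # Q_r equals Q_{r-1}: the matching child is the one flagged
                # saturated under the node we just matched — no new check.
                for cid in node.children:
                    if h.nodes[cid].saturated:
                        child = h.nodes[cid]
                        break
            else:
                matcher = matchers.setdefault(node.node_id, _Matcher(prefilter))
                key = canonical_key(tpl.graph)
                child = matcher.find(tpl.graph, key, lambda n: n.template.graph)
                if child is None:
                    child = h.new_node(tpl, node, saturated=False)
                    matcher.add(child, key)
            if child is None:
                child = h.new_node(tpl, node, saturated=True)
            child.members.append(rid)
            node = child
            prev_tpl = tpl
    return h


def hierarchy_lookup(h: TemplateHierarchy, its: nx.Graph) -> list[int]:
    """Deepest existing node path matched by a reaction's Q_0, Q_1, ...

    Returns node ids from the first matched child of the root downwards;
    empty when the reaction center matches no child of the root.
    """
    center = reaction_center(its)
    path: list[int] = []
    node = h.root
    for r in range(h.max_radius + 1):
        tpl = extend_center(its, center, r)
        nxt = None
        for cid in node.children:
            child = h.nodes[cid]
            if its_isomorphic(child.template.graph, tpl.graph):
                nxt = child
                break
        if nxt is None:
            break
        path.append(nxt.node_id)
        node = nxt
    return path
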