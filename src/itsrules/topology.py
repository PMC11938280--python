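"""Cycle-topology descriptors and classification of reaction centers.

A reaction center decomposes into 2-connected components and a tree-like
remainder.  Each 2-connected component contributes the cycle lengths of a
minimal cycle basis (MCB) — the length multiset is the same for every MCB of
a graph — and each fully acyclic connected component contributes a zero.
Sorted ascending, this list is an isomorphism-invariant descriptor: ``[0]``
acyclic, ``[k]`` a single k-cycle, ``[4, 4]`` two combined 4-cycles,
``[0, 4]`` a hybrid of an acyclic part and a 4-ring.  The descriptor length
doubles as a rough estimate of the number of mechanistic steps: elementary
(single-step) reactions have descriptors ``[0]`` (one component) or ``[k]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx


class EmptyCenterError(ValueError):
    """A center without vertices encodes no mechanism."""


def cycle_descriptor(center: nx.Graph) -> list[int]:
    """Ascending cycle-length list of a reaction center.

    One MCB cycle length per independent cycle of each connected component;
    one 0 per fully acyclic connected component (isolated vertices with a
    hydrogen or charge change included).  Components that contain a cycle
    contribute no 0 for their attached tree-like parts.
    """
    if center.number_of_nodes() == 0:
        raise EmptyCenterError("no mechanism: empty reaction center")
    descriptor: list[int] = []
    for comp_nodes in nx.connected_components(center):
        comp = center.subgraph(comp_nodes)
        n_indep = comp.number_of_edges() - comp.number_of_nodes() + 1
        if n_indep == 0:
            descriptor.append(0)
            continue
        mcb = nx.minimum_cycle_basis(comp)
        descriptor.extend(len(c) for c in mcb)
    return sorted(descriptor)


@dataclass(frozen=True)
class Classification:
    reaction_type: str  # elementary | non-elementary
    topological_type: str  # acyclic | single_cyclic | combinatorial_cyclic | hybrid
    cycle_lengths: tuple[int, ...]
    step_estimate: int


def classify(center: nx.Graph) -> Classification:
    """Classify a reaction center by its cycle descriptor.

    acyclic: all entries 0; single_cyclic: exactly one entry, a cycle;
    combinatorial_cyclic: several cycles and no acyclic part; hybrid: both.
    Elementary (single-step) reactions are ``[0]`` with one component or a
    single cycle ``[k]``; everything longer is non-elementary, with the
    descriptor length estimating the step count.
    """
    desc = tuple(cycle_descriptor(center))
    zeros = sum(1 for d in desc if d == 0)
    cycles = len(desc) - zeros
    if cycles == 0:
        topo = "acyclic"
    elif zeros == 0:
        topo = "single_cyclic" if cycles == 1 else "combinatorial_cyclic"
    else:
        topo = "hybrid"
    elementary = desc == (0,) or (len(desc) == 1 and desc[0] >= 3)
    return Classification(
        reaction_type="elementary" if elementary else "non-elementary",
        topological_type=topo,
        cycle_lengths=desc,
        step_estimate=len(desc),
    )
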