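# Methods

## Model

A reaction is a pair of molecular graphs — reactants G, products H — with an
injective, element-preserving (possibly partial) atom map α.  Vertices carry
element, formal charge and a hydrogen count (implicit hydrogens folded into
the vertex); edges carry a bond order in {1, 2, 3}.  Aromatic systems are
deterministically kekulized on input so bond orders are always comparable
numerically; the perceived aromatic flag is retained on the vertex for
reference.  Explicit hydrogens that carry a map number are kept as vertices
of their own, because mechanistic hydrogens must be present in rewriting
rules; unmapped explicit hydrogens are folded into their neighbour's count,
except in all-hydrogen molecules (H₂), which stay as two-vertex components.

The ITS graph Υ(G, H, α) identifies mapped atom pairs and labels each edge
with the order pair (o_G, o_H), 0 marking absence on one side.  It is built
in one pass over the vertex and edge lists (linear in |V| + |E|).  The
reaction center Γ collects edges with o_G ≠ o_H, their endpoints, and
vertices whose hydrogen count or charge changes.  Radius-r templates Q_r
take every vertex within ITS distance r of Γ together with all induced
edges; Q_0 = Γ, and Q_r ⊆ Q_{r+1} by construction.  Reversal swaps the two
entries of every pair label and is an involution that commutes with center
extraction.

## Isomorphism semantics

Two ITS graphs are equivalent when a label-preserving isomorphism exists.
Vertices match on element, charge pair, and the hydrogen-count *change*
h_H − h_G; edges match on the order pair.  Matching the change rather than
the absolute count is deliberate: substitution outside the reaction center
alters the hydrogen count of a center atom without altering the mechanism,
and the clustering must put, say, all Diels–Alder reactions in one class
regardless of substitution.  Hydrogens that actually move are explicit
vertices after completion, so mechanisms that differ in hydrogen routing
remain distinguishable.  Isomorphism is decided by VF2 (NetworkX); a
Weisfeiler–Lehman hash over the same label abstraction serves as a bucket
prefilter — equal hashes are necessary for isomorphism, never sufficient,
and disabling the prefilter changes no result (this is how isomorphism-call
counts of the two clustering strategies are compared fairly).

For partial atom maps, full-ITS comparison is impossible; when the map
covers the reaction center, radius-r extended centers are compared instead
(default r = 1, configurable).  This condition is necessary but not
sufficient: the acyl- versus alkyl-cleavage maps of an ester hydrolysis
have isomorphic bare centers and only separate at r = 1.  Such false
positives of the r = 0 approximation are known to be rare in practice and
are accepted, not patched.  A partial map that leaves a changed bond
touching an unmapped atom is rejected (detected by comparing, per mapped
vertex, the multiset of (order, partner element) of bonds towards unmapped
atoms on the two sides).

## Hydrogen completion

Per-vertex hydrogen deltas (h_H − h_G) identify donors (negative) and
acceptors (positive); unmapped H₂ components contribute two donor or
acceptor hydrogens bonded to each other on their side.  Every bijection
between donor and acceptor hydrogens — t! pairings for t transferred
hydrogens — yields a candidate completion in which each moved hydrogen
becomes an explicit vertex with one reactant-side and one product-side
incidence.  Candidates are deduplicated by ITS isomorphism: one class means
the completion is unique; several classes mean the mechanism is genuinely
ambiguous and all candidates are returned.  The enumeration is capped
(default 64 pairings; beyond it the reaction is flagged `overflow`).
Ambiguous and overflowing reactions contribute no template by default; a
`keep` mode forwards all candidates tagged as alternatives.  Environmental
hydrogens (solvent) are never imported: only hydrogens present in the
reaction line participate.

## Clustering

Flat clustering iterates over same-radius templates, adding each to the
first cluster whose representative it matches or founding a new one;
first-seen members are representatives, which makes the procedure
deterministic without a chemical prior.  The hierarchy adds a formal root
and matches Q_0, Q_1, … against the children of the already-matched node;
the first radius that matches nothing starts a fresh chain down to the
maximum radius.  Depth-d partitions provably equal flat clustering of all
Q_{d−1}, which the tests assert on every fixture set.  Templates that
saturate (Q_r = Q_{r−1} = full ITS) are carried down without further
isomorphism checks so the per-depth partitions stay well defined at no
extra cost.

## Topology descriptors

A reaction center decomposes into 2-connected components and a tree-like
remainder.  Each cyclic component contributes the cycle lengths of a
minimal cycle basis (all MCBs of a graph share the same length multiset);
each fully acyclic connected component — including isolated vertices whose
only change is a hydrogen or charge — contributes one 0.  A bridge hanging
off a ring adds no 0 (only components without any cycle count).  Sorted
ascending, the descriptor classifies the center: [0] acyclic, [k] single
cyclic, several nonzero entries combinatorial cyclic, mixed entries hybrid.
Descriptor length estimates the number of mechanistic steps; [0]-with-one-
component and [k] are elementary.  The MCB comes from NetworkX's
minimum_cycle_basis; a greedy GF(2) cycle-space oracle cross-checks the
length multiset in the tests.

## Rules and application

A template projects onto a DPO span: L is the reactant-side projection, R
the product side, K all vertices plus the edges with equal order on both
sides.  Rules serialize to MØD-style GML (`rule [ ruleID left [...]
context [...] right [...] ]`, bond labels `-`, `=`, `#`, `:`, charges as
`+`/`-` suffixes on the element).  Node ids follow a canonical order
computed by Weisfeiler–Lehman-style refinement plus exhaustive tie-breaking
over refined orbits (graphs are template-sized, so the automorphism
branching is cheap, with a deterministic fallback behind a branch cap);
isomorphic rules therefore serialize byte-identically.  GML does not encode
hydrogen counts, so the reader recovers a rule up to that attribute; rule
isomorphism is accordingly judged on element, charge and side-wise orders.

Application enumerates injective label-preserving monomorphisms of L into
the substrate.  Substrate hydrogens are first lifted to explicit vertices
so pattern hydrogens can bind; heavy atoms match on element and charge
only — hydrogen counts are not matched, which is what lets a rule extracted
from butadiene fire on isoprene.  Each match deletes the L∖K edges, adds
the R∖K edges, rewrites charges, folds hydrogens back into counts and
canonicalizes the product multiset (RDKit canonical SMILES per component).
A valence guard (C 4, N 3, O 2, S 6, P 5, halogens 1, charge-adjusted,
configurable) silently discards matches whose rewrite oversaturates an
atom — exactly the failure mode of hydrogen-stripped (raw) rules, which
leave the acceptor's old hydrogens in place.  Matches are counted as
distinct placements of the reaction center, a quantity monotone
non-increasing in the radius.

Coverage is the fraction of recorded reactions whose product multiset
(reactant multiset, backward) reappears among rule outputs; novelty is the
fraction of successful (substrate, product) outcomes not isomorphic to any
recorded reaction, judged per isomorphism class of the pair rather than per
embedding.  Hierarchical application matches each top-level radius-0
pattern once and only *extends* those embeddings along each descendant's
nested template chain (template node ids are shared along a chain, so
extension is a small anchored backtracking search).  The product set equals
flat application at every depth while the number of from-scratch pattern
matchings is bounded by the number of top-level classes.

## Synthetic data

The fixture generator emulates balanced, fully mapped single-step organic
reactions from five mechanism families: alkene hydrogenation, Diels–Alder
cycloaddition, Fischer esterification, nucleophilic substitution and amide
condensation.  Each family is a hand-specified core ITS (center descriptor
[4] for the four hydrogen-moving families, [6] for Diels–Alder — the two
dominant classes in real reaction databases) decorated at designated slots
with substituents drawn from a fixed alphabet (methyl, ethyl, propyl,
hydroxymethyl, fluoromethyl, or none) by a seeded RNG, so all members of a
family share an isomorphic center while their contexts differ.  What the
generator does *not* emulate: unbalanced or multi-step reactions,
stereochemistry, aromatic reacting systems, mapping errors, agents.
Passing tests therefore demonstrate the graph-theoretic machinery —
construction, completion, clustering, rewriting — not robustness to the
noise of real mapped data, which enters through the consensus stage when
several independently mapped versions of a reaction are supplied.

## Numerical and design choices

* Default maximum radius 3; extraction cost grows quickly with radius
  because templates approach whole molecules.
* Hydrogen cap 64 pairings; consensus default policy `strict`, comparison
  radius 1; representative of a consensus class is the first source in
  input order (determinism, no chemical prior).
* Acceptance-script problem sizes: 20 reactions per family (100 total),
  radius 0–3 evaluation, chosen as a desk-scale workload that exercises
  every stage.
* Agents in the SMILES agent segment are parsed and ignored.
* Aromatic-order changes without connectivity change count as changed
  edges.
* Degenerate inputs: identity reactions have an empty center and are
  skipped by clustering with a warning; empty-center templates are refused
  by rule emission; an empty reactant or product side is refused at write
  time.

## Known limitations

* No stereochemistry; no isotope-aware chemistry; no coordinates.
* No decomposition of reactions that borrow environmental hydrogens; no
  multistep rule composition or overlay graphs.
* The extended-center equivalence test for partial maps can (rarely) call
  two inequivalent maps equal at small radii.
* H₂-style unmapped components are supported up to two atoms; larger
  all-hydrogen clusters are rejected.
* The GML canonical ordering falls back to a refinement-sorted order if
  the tie-breaking search exceeds its branch cap; the fallback is
  deterministic for a fixed input labeling but not guaranteed canonical
  across relabelings (never observed at template sizes).
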