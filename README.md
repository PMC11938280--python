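# itsrules

Graph-based extraction of reaction templates and rewriting rules from
atom-mapped chemical reactions.

A chemical reaction maps a reactant graph *G* to a product graph *H* through
an atom–atom map (AAM) α : V(G) → V(H).  Superimposing the two sides through
α yields the **imaginary transition state (ITS) graph** Υ(G, H, α): one
vertex per mapped atom pair, one edge per bond present on either side,
labeled with the bond-order pair (o_G, o_H).  Edges with o_G ≠ o_H are the
bonds the reaction makes or breaks; together with atoms whose hydrogen count
or formal charge changes they form the **reaction center** Γ.  Extending Γ
by all atoms within graph distance *r* gives the radius-*r* template Q_r,
which is equivalent to a **double-pushout (DPO) rewriting rule**
L ← K → R: L and R are the two side projections of the template, K the
unchanged context.  Rules apply to new substrates by labeled subgraph
monomorphism and can run backwards by swapping the tuple entries.

`itsrules` implements this stack end to end for anyone building reaction
rule libraries from mapped reaction SMILES:

* parsing/writing of atom-mapped reaction SMILES (RDKit-backed), with
  mechanistic hydrogens kept as explicit vertices;
* ITS construction, reaction-center extraction, radius-r templates,
  reaction reversal;
* completion of hydrogens missing from partial AAMs, with detection of
  ambiguous completions;
* AAM equivalence testing (full-ITS isomorphism, or extended-center
  comparison for partial maps) and ensemble consensus across mapping tools;
* flat and hierarchical clustering of templates into a rule library;
* cycle-topology classification of reaction centers (minimal cycle basis
  per 2-connected component, one 0 per acyclic component);
* DPO rule emission in MØD-style GML, forward/backward application with a
  valence guard, coverage/novelty metrics, and hierarchy-accelerated
  application.

A deterministic generator of balanced, fully mapped single-step reactions
(hydrogenation, Diels–Alder, esterification, nucleophilic substitution,
amide formation) makes every stage testable offline.

## Worked example

```python
from itsrules import (
    parse_mapped_reaction, build_its, reaction_center, template_for,
    template_to_rule, rule_to_gml, apply_rule, invert_rule,
)
from itsrules.dporules import reaction_sides, canonical_molecule_key, fold_hydrogens
from itsrules.topology import classify

rxn = parse_mapped_reaction(
    "[CH2:1]=[CH:2][CH:3]=[CH2:4].[CH2:5]=[CH2:6]"
    ">>[CH2:1]1[CH:2]=[CH:3][CH2:4][CH2:5][CH2:6]1"
)
its = build_its(rxn)
center = reaction_center(its)
print(center.number_of_nodes(), center.number_of_edges())
# 6 6                       <- the six carbons and six changing bonds
print(classify(center).cycle_lengths, classify(center).step_estimate)
# (6,) 1                    <- a single 6-cycle: elementary, one step

rule = template_to_rule(template_for(its, 0), "diels_alder_r0")
substrate, products = reaction_sides(rxn, "forward")
print(apply_rule(rule, substrate))
# {('C1=CCCCC1',)}          <- cyclohexene: the recorded product is recovered

iso_acrylate = parse_mapped_reaction("CC(=C)C=C.C=CC(=O)OC>>CC(=C)C=C.C=CC(=O)OC")
print(sorted(apply_rule(rule, fold_hydrogens(iso_acrylate.reactants))))
# [('COC(=O)C1CC=C(C)CC1',), ('COC(=O)C1CCC=C(C)C1',)]
#                           <- the two regiochemical adducts of isoprene +
#                              methyl acrylate ("para" and "meta")
```

The command-line entry point `itsrules` exposes the same stages
(`fixtures`, `complete`, `aam-check`, `cluster`, `classify`, `apply`,
`run`); `itsrules run --config cfg.yaml --in reactions.smi` executes the
full pipeline and writes a hierarchy JSON, per-radius GML rule files, a
classification TSV and a JSON summary.

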