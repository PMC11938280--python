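import random

import networkx as nx
import pytest

from itsrules.aam_consensus import its_isomorphic
from itsrules.chemio import parse_mapped_reaction
from itsrules.dporules import (
    RuleError,
    apply_rule,
    canonical_molecule_key,
    count_matches,
    evaluate_rules,
    fold_hydrogens,
    hierarchical_apply,
    invert_rule,
    parse_gml,
    reaction_sides,
    rule_isomorphic,
    rule_to_gml,
    strip_hydrogens,
    template_to_rule,
)
from itsrules.its_core import Template, build_its, template_for

from .conftest import DIELS_ALDER, ESTERIFICATION, IDENTITY


def molecules(smiles: str) -> nx.Graph:
    rxn = parse_mapped_reaction(f"{smiles}>>{smiles}")
    return fold_hydrogens(rxn.reactants)


@pytest.fixture(scope="module")
def da_rule():
    its = build_its(parse_mapped_reaction(DIELS_ALDER))
    return template_to_rule(template_for(its, 0), "da_r0")


class TestTemplateToRule:
    def test_diels_alder_span_shape(self, da_rule):
        left_orders = sorted(d["order"] for _, _, d in da_rule.left.edges(data=True))
        right_orders = sorted(d["order"] for _, _, d in da_rule.right.edges(data=True))
        assert left_orders == [1, 2, 2, 2]  # the diene system + the enophile
        assert right_orders == [1, 1, 1, 1, 1, 2]  # the new ring
        assert da_rule.context.number_of_nodes() == 6
        assert da_rule.context.number_of_edges() == 0

    def test_identity_template_refused(self):
        its = build_its(parse_mapped_reaction(IDENTITY))
        with pytest.raises(RuleError, match="no change"):
            template_to_rule(template_for(its, 0))

    def test_esterification_radius_one_context_edges(self):
        its = build_its(parse_mapped_reaction(ESTERIFICATION))
        rule = template_to_rule(template_for(its, 1))
        assert rule.context.number_of_nodes() == 8
        # unchanged bonds: C=O carbonyl, acyl C-C, acid O-H, alcohol O-C
        assert sorted(
            d["order"] for _, _, d in rule.context.edges(data=True)
        ) == [1, 1, 1, 2]

    def test_rule_reconstructs_template_its(self, fixture_its):
        """Fusing L and R back into one pair-labeled graph recovers the
        template, confirming the DPO span / partial-ITS equivalence."""
        for _, _, its in fixture_its[:5]:
            tpl = template_for(its, 1)
            rule = template_to_rule(tpl)
            fused = nx.Graph(free_h_reactant=(), free_h_product=())
            for n in rule.context.nodes:
                fused.add_node(
                    n,
                    element=rule.left.nodes[n]["element"],
                    charge=(rule.left.nodes[n]["charge"], rule.right.nodes[n]["charge"]),
                    hcount=(rule.left.nodes[n]["hcount"], rule.right.nodes[n]["hcount"]),
                    aromatic=(False, False),
                )
            for u, v in set(rule.left.edges) | set(rule.right.edges):
                ol = rule.left.edges[u, v]["order"] if rule.left.has_edge(u, v) else 0
                orr = rule.right.edges[u, v]["order"] if rule.right.has_edge(u, v) else 0
                fused.add_edge(u, v, order=(ol, orr))
            assert its_isomorphic(fused, tpl.graph)


class TestGml:
    def test_round_trip_is_rule_isomorphic(self, da_rule):
        assert rule_isomorphic(da_rule, parse_gml(rule_to_gml(da_rule)))

    def test_vertex_permutation_gives_identical_bytes(self, fixture_its):
        rng = random.Random(17)
        for _, _, its in fixture_its[:6]:
            tpl = template_for(its, 1)
            perm = dict(
                zip(tpl.graph.nodes, rng.sample(list(tpl.graph.nodes), tpl.graph.number_of_nodes()))
            )
            permuted = Template(
                graph=nx.relabel_nodes(tpl.graph, perm),
                radius=tpl.radius,
                center_nodes=frozenset(perm[n] for n in tpl.center_nodes),
            )
            assert rule_to_gml(template_to_rule(tpl, "x")) == rule_to_gml(
                template_to_rule(permuted, "x")
            )

    def test_serialization_is_stable_across_calls(self, da_rule):
        assert rule_to_gml(da_rule) == rule_to_gml(da_rule)

    def test_changed_edges_live_in_left_and_right_only(self, da_rule):
        text = rule_to_gml(da_rule)
        context_section = text.split("context [")[1].split("right [")[0]
        assert "edge" not in context_section  # all six DA bonds change
        assert context_section.count("node") == 6


class TestApply:
    def test_source_reaction_round_trip(self, da_rule):
        rxn = parse_mapped_reaction(DIELS_ALDER)
        sub, prod = reaction_sides(rxn, "forward")
        assert canonical_molecule_key(prod) in apply_rule(da_rule, sub)

    def test_regiochemistry_product_counts(self, da_rule):
        assert len(apply_rule(da_rule, molecules("CC(=C)C=C.C=C"))) == 1
        assert len(apply_rule(da_rule, molecules("CC(=C)C=C.C=CC(=O)OC"))) == 2

    def test_no_embedding_no_products(self, da_rule):
        assert apply_rule(da_rule, molecules("C")) == set()

    def test_inversion_is_involution(self, da_rule):
        double = invert_rule(invert_rule(da_rule))
        assert rule_to_gml(double) == rule_to_gml(da_rule)

    def test_inverted_rule_retro_reaction(self, da_rule):
        out = apply_rule(invert_rule(da_rule), molecules("C1=CCCCC1"))
        assert canonical_molecule_key(molecules("C=CC=C.C=C")) in out

    def test_embedding_count_non_increasing_with_radius(self, fixture_its, fixture_reactions):
        for (i, _, its), (_, rxn) in list(zip(fixture_its, fixture_reactions))[:10]:
            sub, _ = reaction_sides(rxn, "forward")
            counts = [
                count_matches(template_to_rule(template_for(its, r)), sub)
                for r in range(4)
            ]
            assert all(a >= b for a, b in zip(counts, counts[1:])), counts
            assert counts[0] >= 1


class TestRawRules:
    def test_hydrogen_stripped_rule_fails_by_valence(self):
        """Ignoring moved hydrogens leaves the alcohol oxygen with three
        bonds after the rewrite, so the valence guard rejects every match."""
        rxn = parse_mapped_reaction(ESTERIFICATION)
        its = build_its(rxn)
        sub, prod = reaction_sides(rxn, "forward")
        for r in (0, 1):
            complete = template_to_rule(template_for(its, r))
            raw = template_to_rule(strip_hydrogens(template_for(its, r)))
            assert canonical_molecule_key(prod) in apply_rule(complete, sub)
            assert canonical_molecule_key(prod) not in apply_rule(raw, sub)
        # with one shell of context the pattern can only sit on the true
        # acid/alcohol site, and there every rewrite is valence-rejected
        raw1 = template_to_rule(strip_hydrogens(template_for(its, 1)))
        assert apply_rule(raw1, sub) == set()

    def test_hydrogen_free_mechanism_unaffected_by_stripping(self, da_rule):
        rxn = parse_mapped_reaction(DIELS_ALDER)
        its = build_its(rxn)
        raw = template_to_rule(strip_hydrogens(template_for(its, 0)))
        sub, prod = reaction_sides(rxn, "forward")
        assert canonical_molecule_key(prod) in apply_rule(raw, sub)


class TestEvaluate:
    def test_self_consistency_round_trip(self, fixture_its, fixture_reactions):
        reactions = [rxn for _, rxn in fixture_reactions[:10]]
        rules = [
            template_to_rule(template_for(its, 1), f"r{i}")
            for (i, _, its) in fixture_its[:10]
        ]
        rule_map = {i: f"r{i}" for i in range(10)}
        for direction in ("forward", "backward"):
            m = evaluate_rules(rules, reactions, direction, rule_map=rule_map)
            assert m.coverage == 1.0, direction

    def test_foreign_rule_recovers_nothing(self, da_rule, fixture_reactions):
        hydrogenations = [r for fam, r in fixture_reactions if fam == "hydrogenation"]
        m = evaluate_rules([da_rule], hydrogenations, "forward")
        assert m.coverage == 0.0

    def test_novelty_counts_unrecorded_outcomes(self, da_rule):
        recorded = [parse_mapped_reaction(DIELS_ALDER)]
        m = evaluate_rules(
            [da_rule],
            recorded,
            "forward",
            extra_substrates=[molecules("CC(=C)C=C.C=C")],
        )
        assert (m.recovered, m.attempted) == (1, 1)
        assert (m.novel, m.successful) == (1, 2)
        assert m.coverage == 1.0 and m.novelty == 0.5

    def test_empty_reaction_list_rejected(self, da_rule):
        with pytest.raises(ValueError):
            evaluate_rules([da_rule], [], "forward")


@pytest.fixture(scope="module")
def hierarchy(fixture_its):
    from itsrules.clustering import build_hierarchy

    return build_hierarchy([(i, its) for i, _, its in fixture_its], 2)


class TestHierarchicalApply:
    def test_product_sets_equal_flat_at_every_depth(self, hierarchy, fixture_reactions):
        for depth in range(3):
            level = hierarchy.levels()[depth]
            rules = [template_to_rule(n.template, f"n{n.node_id}") for n in level]
            for _, rxn in fixture_reactions[:6]:
                sub, _ = reaction_sides(rxn, "forward")
                flat = set()
                for r in rules:
                    flat |= apply_rule(r, sub)
                hier, attempts = hierarchical_apply(hierarchy, sub, depth)
                assert hier == flat
                assert attempts <= len(rules)

    def test_unmatched_substrate_prunes_early(self, hierarchy):
        products, attempts = hierarchical_apply(hierarchy, molecules("C"), 2)
        assert products == set()
        assert attempts == len(hierarchy.root.children)

    def test_depth_beyond_hierarchy_rejected(self, hierarchy):
        with pytest.raises(ValueError):
            hierarchical_apply(hierarchy, molecules("C"), 9)
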