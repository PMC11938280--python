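import random

import pytest

from itsrules.aam_consensus import (
    BadMappingError,
    _edge_match,
    _node_match,
    aam_equivalent,
    ensemble_consensus,
    its_isomorphic,
)
from itsrules.chemio import parse_mapped_reaction
from itsrules.its_core import build_its, template_for

from ._oracles import brute_force_isomorphic, permuted_copy, random_its_like_graph
from .conftest import DIELS_ALDER

# the same hydrogenation, mapped with the two equivalent hydrogens swapped
HYDROG_A = "[CH2:1]=[CH2:2].[H:3][H:4]>>[CH2:1]([H:3])[CH2:2][H:4]"
HYDROG_B = "[CH2:1]=[CH2:2].[H:3][H:4]>>[CH2:1]([H:4])[CH2:2][H:3]"
# ester hydrolysis mapped with acyl-oxygen cleavage (the accepted mechanism)
# versus alkyl-oxygen cleavage: same unmapped reaction, different mechanism
ACYL_CLEAVAGE = (
    "[C:1](=[O:2])([O:3][CH3:4])[CH3:5].[O:6]([H:7])[H:8]"
    ">>[C:1](=[O:2])([O:6][H:8])[CH3:5].[O:3]([H:7])[CH3:4]"
)
ALKYL_CLEAVAGE = (
    "[C:1](=[O:2])([O:3][CH3:4])[CH3:5].[O:6]([H:7])[H:8]"
    ">>[C:1](=[O:2])([O:3][H:7])[CH3:5].[O:6]([H:8])[CH3:4]"
)


class TestItsIsomorphic:
    def test_reflexive_and_permutation_invariant(self):
        rng = random.Random(3)
        for _ in range(10):
            g = random_its_like_graph(rng, rng.randint(2, 7))
            assert its_isomorphic(g, g)
            assert its_isomorphic(g, permuted_copy(g, rng))

    def test_agrees_with_brute_force_oracle(self):
        rng = random.Random(5)
        graphs = [random_its_like_graph(rng, rng.randint(2, 6)) for _ in range(10)]
        graphs += [permuted_copy(g, rng) for g in graphs[:5]]
        for a in graphs:
            for b in graphs:
                assert its_isomorphic(a, b) == brute_force_isomorphic(
                    a, b, _node_match, _edge_match
                )

    def test_equivalence_relation_on_fixture_triples(self, fixture_its):
        rng = random.Random(9)
        graphs = [its for _, _, its in fixture_its[:6]]
        graphs.append(permuted_copy(graphs[0], rng))
        for a in graphs:
            assert its_isomorphic(a, a)
            for b in graphs:
                assert its_isomorphic(a, b) == its_isomorphic(b, a)
                for c in graphs:
                    if its_isomorphic(a, b) and its_isomorphic(b, c):
                        assert its_isomorphic(a, c)

    def test_single_label_change_detected(self):
        rng = random.Random(11)
        g = random_its_like_graph(rng, 6)
        h = g.copy()
        n = next(iter(h.nodes))
        hg, hh = h.nodes[n]["hcount"]
        h.nodes[n]["hcount"] = (hg, hh + 1)  # changes the hydrogen delta
        assert not its_isomorphic(g, h)


class TestAamEquivalent:
    def test_renumbering_invariance(self):
        a = parse_mapped_reaction(DIELS_ALDER)
        renum = DIELS_ALDER
        for old, new in zip("123456", "642531"):
            renum = renum.replace(f":{old}]", f":x{new}]")
        renum = renum.replace(":x", ":")
        b = parse_mapped_reaction(renum)
        assert aam_equivalent(a, b)

    def test_equivalent_hydrogen_swap(self):
        assert aam_equivalent(
            parse_mapped_reaction(HYDROG_A), parse_mapped_reaction(HYDROG_B)
        )

    def test_non_equivalent_complete_maps_fail_at_every_radius(self):
        a = parse_mapped_reaction(
            "[CH2:1]=[CH:2][OH:3].[H:4][Cl:5]>>[CH3:1][CH:2]=[O:3].[H:4][Cl:5]"
        )
        b = parse_mapped_reaction(
            "[CH2:1]=[CH:2][O:3][H:4].[H][Cl:5]>>[CH3:1][CH:2]=[O:3].[H:4][Cl:5]"
        )
        assert not its_isomorphic(
            build_its(a), build_its(b, allow_partial=True)
        )
        for r in range(4):
            ta = template_for(build_its(a), r)
            tb = template_for(build_its(b, allow_partial=True), r)
            assert not its_isomorphic(ta.graph, tb.graph)

    def test_acyl_vs_alkyl_cleavage_maps_differ(self):
        """Two maps of one hydrolysis with different bond-breaking sites
        give non-isomorphic ITS graphs, although their bare 4-cycle centers
        coincide (the known blind spot of the radius-0 approximation)."""
        a = parse_mapped_reaction(ACYL_CLEAVAGE)
        b = parse_mapped_reaction(ALKYL_CLEAVAGE)
        assert not aam_equivalent(a, b)
        t0a = template_for(build_its(a), 0)
        t0b = template_for(build_its(b), 0)
        assert its_isomorphic(t0a.graph, t0b.graph)
        t1a = template_for(build_its(a), 1)
        t1b = template_for(build_its(b), 1)
        assert not its_isomorphic(t1a.graph, t1b.graph)

    def test_partial_maps_compared_by_extended_centers(self):
        full = parse_mapped_reaction(HYDROG_A)
        partial = parse_mapped_reaction(
            "[CH2:1]=[CH2:2].[H:3][H:4]>>[CH2:1]([H:3])[CH2:2][H:4].".rstrip(".")
        )
        assert aam_equivalent(full, partial, r=1)

    def test_partial_map_missing_center_atom_rejected(self):
        # the forming C-O bond touches the unmapped alcohol oxygen
        a = parse_mapped_reaction("[CH3:1]Cl>>[CH3:1]OC")
        b = parse_mapped_reaction("[CH3:1]Cl>>[CH3:1]OC")
        with pytest.raises(BadMappingError):
            aam_equivalent(a, b)

    def test_extended_center_mismatch_is_monotone_in_radius(self, fixture_reactions):
        """Once extended centers differ at radius r they differ at r' > r."""
        pairs = [(a, b) for (_, a) in fixture_reactions[:6] for (_, b) in fixture_reactions[:6]]
        for a, b in pairs:
            verdicts = [
                its_isomorphic(
                    template_for(build_its(a), r).graph,
                    template_for(build_its(b), r).graph,
                )
                for r in range(4)
            ]
            # False never flips back to True
            assert all(
                later or not earlier
                for earlier, later in zip(verdicts, verdicts)
            )
            for r in range(3):
                if not verdicts[r]:
                    assert not verdicts[r + 1]


class TestConsensus:
    def test_unanimous_sources(self):
        sources = [
            parse_mapped_reaction(HYDROG_A),
            parse_mapped_reaction(HYDROG_B),
            parse_mapped_reaction(HYDROG_A),
        ]
        res = ensemble_consensus(sources)
        assert res.status == "consensus"
        assert res.winning_sources == [0, 1, 2]
        assert its_isomorphic(res.representative, build_its(sources[0]))

    def test_majority_two_against_one(self):
        sources = [
            parse_mapped_reaction(ACYL_CLEAVAGE),
            parse_mapped_reaction(ACYL_CLEAVAGE),
            parse_mapped_reaction(ALKYL_CLEAVAGE),
        ]
        strict = ensemble_consensus(sources, policy="strict")
        major = ensemble_consensus(sources, policy="majority")
        assert strict.status == "disagreement" and strict.representative is None
        assert major.status == "consensus"
        assert major.winning_sources == [0, 1]

    def test_order_invariance_of_partition(self):
        base = [ACYL_CLEAVAGE, ACYL_CLEAVAGE, ALKYL_CLEAVAGE]
        statuses = set()
        for perm in ([0, 1, 2], [2, 0, 1], [1, 2, 0]):
            sources = [parse_mapped_reaction(base[i]) for i in perm]
            statuses.add(ensemble_consensus(sources, policy="majority").status)
        assert statuses == {"consensus"}

    def test_different_reactions_rejected(self):
        with pytest.raises(ValueError, match="same unmapped reaction"):
            ensemble_consensus(
                [
                    parse_mapped_reaction(HYDROG_A),
                    parse_mapped_reaction(DIELS_ALDER),
                ]
            )

    def test_fewer_than_two_sources_rejected(self):
        with pytest.raises(ValueError):
            ensemble_consensus([parse_mapped_reaction(HYDROG_A)])
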