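"""Mutation counting: step differences, multi-copy matching, DYS389
derivation and trio parsimony."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_haplotype, make_pair_pedigree

from ystrped.counting import (AmbiguousComparison, count_mutations_genealogy,
                              count_mutations_pair, derive_dys389,
                              multicopy_difference, step_difference)


class TestStepDifference:
    @pytest.mark.parametrize("a,b,expected", [
        (14, 14, 0),
        (14, 16, 2),
        (16, 14, -2),
        (13.2, 14.2, 1),
    ])
    def test_signed_steps(self, a, b, expected):
        assert step_difference(a, b) == expected

    def test_incommensurable_alleles_flagged(self):
        with pytest.raises(AmbiguousComparison):
            step_difference(13.2, 14)


class TestMulticopyDifference:
    @pytest.mark.parametrize("m1,m2,expected", [
        ((15, 17), (15, 17), (0, 0, False)),
        ((15, 17), (15, 18), (1, 1, False)),
        # both bijections give total 2 steps with 2 events: a tie on the
        # event count is not ambiguous
        ((13, 15), (14, 14), (2, 2, False)),
    ])
    def test_minimal_matching(self, m1, m2, expected):
        assert multicopy_difference(m1, m2) == expected

    def test_unequal_copy_numbers_ambiguous(self):
        assert multicopy_difference((15,), (15, 17))[2] is True

    @given(st.lists(st.integers(8, 24), min_size=2, max_size=3),
           st.lists(st.integers(8, 24), min_size=2, max_size=3))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_assignment_oracle(self, m1, m2):
        """Independent oracle: enumerate index permutations directly on the
        unsorted inputs and minimise (total, then events)."""
        total, events, ambiguous = multicopy_difference(tuple(m1), tuple(m2))
        if len(m1) != len(m2):
            assert ambiguous
            return
        options = []
        for perm in itertools.permutations(range(len(m2))):
            steps = [abs(m2[j] - a) for a, j in zip(m1, perm)]
            options.append((sum(steps), sum(1 for s in steps if s)))
        best_total = min(t for t, _ in options)
        event_set = {e for t, e in options if t == best_total}
        if len(event_set) == 1:
            assert not ambiguous
            assert (total, events) == (best_total, event_set.pop())
        else:
            assert ambiguous

    @given(st.lists(st.integers(8, 24), min_size=2, max_size=4),
           st.lists(st.integers(8, 24), min_size=2, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_identity_and_symmetry(self, m1, m2):
        m1, m2 = tuple(m1), tuple(m2)
        assert multicopy_difference(m1, m1) == (0, 0, False)
        # a shared-ancestor comparison cannot depend on orientation
        assert multicopy_difference(m1, m2) == multicopy_difference(m2, m1)


class TestDeriveDys389:
    def test_subtraction(self):
        hap = make_haplotype("S1", {"DYS389I": (13.0,), "DYS389II": (29.0,)})
        derived = derive_dys389(hap)
        assert derived.alleles["DYS389II-I"] == (16.0,)
        assert "DYS389II" not in derived.alleles

    def test_shared_mutation_counted_once(self, registry):
        # A mutation in the DYS389I stretch shifts DYS389II too; after
        # subtraction only DYS389I registers it.
        h1 = make_haplotype("S1", {"DYS389I": (13.0,), "DYS389II": (29.0,)})
        h2 = make_haplotype("S2", {"DYS389I": (14.0,), "DYS389II": (30.0,)})
        obs = {o.locus: o for o in count_mutations_pair(h1, h2, registry)}
        assert obs["DYS389I"].events_single == 1
        assert obs["DYS389II-I"].events_single == 0

    def test_independent_dys389ii_mutation(self, registry):
        h1 = make_haplotype("S1", {"DYS389I": (13.0,), "DYS389II": (29.0,)})
        h2 = make_haplotype("S2", {"DYS389I": (13.0,), "DYS389II": (31.0,)})
        obs = {o.locus: o for o in count_mutations_pair(h1, h2, registry)}
        assert obs["DYS389II-I"].events_single == 1
        assert obs["DYS389II-I"].events_multi == 2

    def test_missing_partner_drops_both(self):
        hap = make_haplotype("S1", {"DYS389I": (13.0,), "DYS19": (14.0,)})
        derived = derive_dys389(hap)
        assert "DYS389I" not in derived.alleles
        assert "DYS389II-I" not in derived.alleles
        assert derived.alleles["DYS19"] == (14.0,)


class TestPairCounting:
    def test_identical_haplotypes_all_zero(self, registry):
        alleles = {"DYS19": (14.0,), "DYS390": (24.0,), "DYS385": (11.0, 14.0)}
        h1 = make_haplotype("S1", dict(alleles))
        h2 = make_haplotype("S2", dict(alleles))
        obs = count_mutations_pair(h1, h2, registry)
        assert sum(o.events_multi for o in obs) == 0

    def test_two_step_difference_modes(self, registry):
        h1 = make_haplotype("S1", {"DYS19": (14.0,), "DYS390": (24.0,)})
        h2 = make_haplotype("S2", {"DYS19": (16.0,), "DYS390": (24.0,)})
        obs = count_mutations_pair(h1, h2, registry)
        assert sum(o.events_single for o in obs) == 1
        assert sum(o.events_multi for o in obs) == 2

    def test_ambiguous_locus_excluded_others_counted(self, registry):
        h1 = make_haplotype("S1", {"DYS385": (11.0,), "DYS19": (14.0,)})
        h2 = make_haplotype("S2", {"DYS385": (11.0, 14.0), "DYS19": (15.0,)})
        obs = {o.locus: o for o in count_mutations_pair(h1, h2, registry)}
        assert obs["DYS385"].ambiguous
        assert obs["DYS19"].events_single == 1

    @given(a=st.integers(8, 30), b=st.integers(8, 30))
    @settings(max_examples=50, deadline=None)
    def test_modes_ordered(self, registry, a, b):
        h1 = make_haplotype("S1", {"DYS19": (float(a),)})
        h2 = make_haplotype("S2", {"DYS19": (float(b),)})
        (obs,) = count_mutations_pair(h1, h2, registry)
        assert obs.events_multi >= obs.events_single >= 0
        assert obs.events_single == (1 if a != b else 0)
        assert obs.events_multi == abs(a - b)


class TestGenealogyCounting:
    def _trio_haps(self, a, b, d, locus="DYS19"):
        return {
            "T1.a": make_haplotype("T1.a", {locus: (float(a),)}, "T1"),
            "T1.b": make_haplotype("T1.b", {locus: (float(b),)}, "T1"),
            "T1.d": make_haplotype("T1.d", {locus: (float(d),)}, "T1"),
        }

    def test_trio_outermost_variant_is_one_mutation(self, registry, trio_pedigree):
        # The outgroup (branch a) carries 15, the inner pair 14: a single
        # mutation on the outgroup branch explains the data.
        haps = self._trio_haps(15, 14, 14)
        count = count_mutations_genealogy(trio_pedigree, haps, registry)
        assert count.events_single["DYS19"] == 1
        assert count.events_multi["DYS19"] == 1

    def test_trio_inner_pair_variant(self, registry, trio_pedigree):
        # One inner leaf differs: one mutation on its private branch.
        haps = self._trio_haps(14, 14, 16)
        count = count_mutations_genealogy(trio_pedigree, haps, registry)
        assert count.events_single["DYS19"] == 1
        assert count.events_multi["DYS19"] == 2

    def test_trio_identical_zero(self, registry, trio_pedigree):
        haps = self._trio_haps(14, 14, 14)
        count = count_mutations_genealogy(trio_pedigree, haps, registry)
        assert count.total("multi") == 0

    def test_trio_meioses_is_tree_total(self, registry, trio_pedigree):
        haps = self._trio_haps(14, 14, 14)
        count = count_mutations_genealogy(trio_pedigree, haps, registry)
        assert count.meioses == trio_pedigree.tree_meioses() == 15

    @given(a=st.integers(10, 20), b=st.integers(10, 20))
    @settings(max_examples=50, deadline=None)
    def test_pair_genealogy_reduces_to_pair_counting(self, registry, a, b):
        ped = make_pair_pedigree()
        haps = {
            "L1.a": make_haplotype("L1.a", {"DYS19": (float(a),)}),
            "L1.b": make_haplotype("L1.b", {"DYS19": (float(b),)}),
        }
        count = count_mutations_genealogy(ped, haps, registry)
        obs = count_mutations_pair(haps["L1.a"], haps["L1.b"], registry)[0]
        assert count.events_single.get("DYS19", 0) == obs.events_single
        assert count.events_multi.get("DYS19", 0) == obs.events_multi
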