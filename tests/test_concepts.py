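"""FCA machinery: closure, attribute concepts, organizations, cores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import orglattice as ol
from orglattice.errors import ValidationError

from oracles import brute_additional, brute_concepts, brute_intents


def table_from_sets(universe, sets, well="H41"):
    recs = [
        ol.SampleRecord(f"{well}:{i}", well, i, s) for i, s in enumerate(sets)
    ]
    return ol.MeasurementTable(universe, recs)


def random_context(seed, n_samples, n_taxa=8):
    rng = np.random.default_rng(seed)
    u = ol.TaxaUniverse([f"t{i}" for i in range(n_taxa)])
    sets = [
        ol.TaxaSet(u, int(rng.integers(1, 2**n_taxa)))
        for _ in range(n_samples)
    ]
    return table_from_sets(u, sets), u


class TestIntersectionClosure:
    def test_three_overlapping_sets(self):
        u = ol.TaxaUniverse(list("abcd"))
        sets = [u.set_of("abc"), u.set_of("abd"), u.set_of("acd")]
        got = {s.labels() for s in ol.intersection_closure(sets)}
        assert got == {
            ("a", "b", "c"),
            ("a", "b", "d"),
            ("a", "c", "d"),
            ("a", "b"),
            ("a", "c"),
            ("a", "d"),
            ("a",),
        }

    def test_single_set_closure_is_itself(self, abc_universe):
        s = abc_universe.set_of("ab")
        assert ol.intersection_closure([s]) == [s]

    def test_deterministic_order_size_then_lex(self, abc_universe):
        u = abc_universe
        out = ol.intersection_closure([u.set_of("ab"), u.set_of("ac")])
        assert [s.labels() for s in out] == [("a", "b"), ("a", "c"), ("a",)]

    @given(st.integers(0, 10**6))
    @settings(max_examples=30)
    def test_equals_all_subset_intersections_oracle(self, seed):
        table, _ = random_context(seed, n_samples=(seed % 10) + 3)
        got = {
            frozenset(s.labels())
            for s in ol.intersection_closure(table.taxa_sets())
        }
        expect = brute_intents(
            [frozenset(s.labels()) for s in table.taxa_sets()]
        )
        assert got == expect

    def test_idempotent(self, abc_universe):
        u = abc_universe
        once = ol.intersection_closure([u.set_of("abx"), u.set_of("aby"), u.set_of("acx")])
        assert ol.intersection_closure(once) == once


class TestAttributeConcept:
    def test_two_sample_intersection(self):
        u = ol.TaxaUniverse(list("abcd"))
        table = table_from_sets(u, [u.set_of("abd"), u.set_of("acd")])
        assert ol.attribute_concept("d", table) == u.set_of("ad")

    def test_taxon_in_single_sample_yields_full_set(self):
        u = ol.TaxaUniverse(list("abcd"))
        table = table_from_sets(u, [u.set_of("abd"), u.set_of("ac")])
        assert ol.attribute_concept("b", table) == u.set_of("abd")

    def test_ubiquitous_taxon_maps_to_global_intersection(self):
        u = ol.TaxaUniverse(list("abcd"))
        table = table_from_sets(u, [u.set_of("abd"), u.set_of("acd"), u.set_of("ad")])
        assert ol.attribute_concept("a", table) == u.set_of("ad")

    def test_unobserved_taxon_rejected(self):
        u = ol.TaxaUniverse(list("abcd"))
        table = table_from_sets(u, [u.set_of("ab")])
        with pytest.raises(ValidationError):
            ol.attribute_concept("c", table)


class TestIntroducingSets:
    def test_two_sample_example(self):
        u = ol.TaxaUniverse(list("abc"))
        table = table_from_sets(u, [u.set_of("ab"), u.set_of("ac")])
        got = {
            s.labels(): intro.labels() for s, intro in ol.introducing_sets(table)
        }
        assert got == {
            ("a",): ("a",),
            ("a", "b"): ("b",),
            ("a", "c"): ("c",),
        }

    def test_identical_samples_single_concept(self, abc_universe):
        u = abc_universe
        table = table_from_sets(u, [u.set_of("abx")] * 3)
        got = ol.introducing_sets(table)
        assert len(got) == 1
        assert got[0][0] == u.set_of("abx") and got[0][1] == u.set_of("abx")


class TestAdditionalOrganizations:
    def test_motif(self, motif_table, abc_universe):
        assert ol.additional_organizations(motif_table) == [
            abc_universe.set_of("abc")
        ]

    def test_antichain_yields_none(self, abc_universe):
        u = abc_universe
        assert ol.additional_organizations([u.set_of("ab"), u.set_of("cx")]) == []

    def test_union_condition_requires_two_subset_measurements(
        self, abc_universe
    ):
        # drop one of the union witnesses: {a,b,c} is still a cut of two
        # measurements but no longer a union of two
        u = abc_universe
        sets = [u.set_of("ab"), u.set_of("abcx"), u.set_of("abcy")]
        assert ol.additional_organizations(sets) == []

    @given(st.integers(0, 10**6))
    @settings(max_examples=40)
    def test_matches_brute_force_intent_scan(self, seed):
        table, _ = random_context(seed, n_samples=(seed % 8) + 3, n_taxa=6)
        got = [
            frozenset(s.labels())
            for s in ol.additional_organizations(table.taxa_sets())
        ]
        expect = brute_additional(
            [frozenset(s.labels()) for s in table.taxa_sets()]
        )
        assert sorted(got, key=sorted) == sorted(
            [set(e) for e in expect], key=sorted
        )


class TestGaloisProperty:
    @given(st.integers(0, 10**6))
    @settings(max_examples=25)
    def test_concepts_are_mutual_fixpoints(self, seed):
        table, u = random_context(seed, n_samples=(seed % 9) + 3)
        sample_sets = {
            rec.sample_id: frozenset(rec.taxa.labels()) for rec in table.samples
        }
        expect = brute_concepts(sample_sets)
        # package route: intents from the closure, extents by support scan
        for intent in ol.intersection_closure(table.taxa_sets()):
            extent = frozenset(
                rec.sample_id
                for rec in table.samples
                if intent <= rec.taxa
            )
            assert (extent, frozenset(intent.labels())) in expect


class TestCoreMicrobiomes:
    def test_two_concepts_at_ninety_percent(self):
        u = ol.TaxaUniverse(list("ab"))
        sets = [u.set_of("ab")] * 9 + [u.set_of("a")]
        table = table_from_sets(u, sets)
        cores = ol.core_microbiomes(table, support_fraction=0.9)
        by_intent = {c.intent.labels(): c.support for c in cores}
        assert by_intent == {("a",): 10, ("a", "b"): 9}
        assert ol.largest_core(cores).intent == u.set_of("ab")
        assert ol.smallest_core(cores).intent == u.set_of("a")

    def test_full_support_is_global_intersection(self, motif_table):
        cores = ol.core_microbiomes(motif_table, support_fraction=1.0)
        assert len(cores) == 1
        assert cores[0].intent.labels() == ("a",)

    def test_fraction_out_of_range_rejected(self, motif_table):
        with pytest.raises(ValidationError):
            ol.core_microbiomes(motif_table, support_fraction=0.0)

    @given(st.integers(0, 10**6))
    @settings(max_examples=20)
    def test_monotone_in_support_fraction(self, seed):
        table, _ = random_context(seed, n_samples=(seed % 10) + 4)
        counts = [
            len(ol.core_microbiomes(table, support_fraction=f))
            for f in (0.5, 0.7, 0.9, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestSignificantLattice:
    def test_motif_lattice_kinds_and_flags(self, motif_table, abc_universe):
        u = abc_universe
        h = ol.significant_lattice(motif_table)
        kinds = {n.taxa.labels(): n.kind for n in h.nodes}
        assert kinds[("a", "b", "c")] == "additional_organization"
        assert kinds[("a", "b")] == "measurement"
        assert kinds[("a",)] == "intersection"
        assert kinds[()] == "bottom"
        # grey-background semantics: measurements and additional
        # organizations are self-maintaining, plain intersections are not
        for n in h.nodes:
            assert n.is_self_maintaining == (
                n.kind in ("measurement", "additional_organization")
            )

    def test_motif_counts(self, motif_table):
        h = ol.significant_lattice(motif_table)
        kinds = [n.kind for n in h.nodes]
        assert kinds.count("measurement") == 4
        assert kinds.count("additional_organization") == 1

    def test_single_measurement(self, abc_universe):
        u = abc_universe
        table = table_from_sets(u, [u.set_of("ab")])
        h = ol.significant_lattice(table)
        kinds = [n.kind for n in h.nodes]
        assert kinds.count("measurement") == 1
        assert kinds.count("additional_organization") == 0

    def test_measurement_nodes_support_well_times(self, motif_table):
        h = ol.significant_lattice(motif_table)
        node = next(
            n for n in h.nodes if n.kind == "additional_organization"
        )
        # {a,b,c} is contained in the two large measurements
        assert set(node.support) == {"H41:2", "H41:3"}
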