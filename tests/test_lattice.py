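"""Subset-order analytics: Hasse construction, paths, connectivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import orglattice as ol
from orglattice.errors import CapacityError, ValidationError

from oracles import brute_cover_edges, brute_paths, brute_subset_pairs


def universe10():
    return ol.TaxaUniverse([f"t{i}" for i in range(10)])


def random_sets(seed, n_sets, n_taxa=10):
    rng = np.random.default_rng(seed)
    u = ol.TaxaUniverse([f"t{i}" for i in range(n_taxa)])
    return [
        ol.TaxaSet(u, int(rng.integers(0, 2**n_taxa))) for _ in range(n_sets)
    ], u


class TestSubsetPairs:
    def test_single_relation(self, abc_universe):
        u = abc_universe
        sets = [u.set_of("a"), u.set_of("ab"), u.set_of("c")]
        assert ol.subset_pairs(sets) == [(0, 1)]

    def test_antichain_has_no_pairs(self, abc_universe):
        u = abc_universe
        assert ol.subset_pairs([u.set_of("ab"), u.set_of("cx"), u.set_of("ay")]) == []

    @given(st.integers(0, 10**6))
    @settings(max_examples=40)
    def test_matches_brute_force(self, seed):
        sets, _ = random_sets(seed, 20)
        ds = ol.distinct_sets(sets)
        expect = brute_subset_pairs([frozenset(s.labels()) for s in ds])
        assert sorted(ol.subset_pairs(sets)) == sorted(expect)


class TestBuildHasse:
    def test_bounded_three_set_example(self, abc_universe):
        u = abc_universe
        h = ol.build_hasse(
            [u.set_of("a"), u.set_of("ab"), u.set_of("c")], include_bounds=True
        )
        by_taxa = {n.taxa.labels(): n.node_id for n in h.nodes}
        assert set(by_taxa) == {(), ("a",), ("c",), ("a", "b"), ("a", "b", "c")}
        expect = {
            ((), ("a",)),
            ((), ("c",)),
            (("a",), ("a", "b")),
            (("a", "b"), ("a", "b", "c")),
            (("c",), ("a", "b", "c")),
        }
        inv = {v: k for k, v in by_taxa.items()}
        assert {(inv[u_], inv[v_]) for u_, v_ in h.edges} == expect

    def test_single_set_with_bounds(self, abc_universe):
        # the top (union of all sets) coincides with the lone set, so
        # only the virtual bottom is added
        h = ol.build_hasse([abc_universe.set_of("ab")], include_bounds=True)
        assert h.n_nodes == 2 and len(h.edges) == 1

    @pytest.mark.parametrize("k", [2, 4, 7])
    def test_nested_chain_with_bounds(self, k):
        u = universe10()
        chain = [u.set_of(list(range(1, i + 2))) for i in range(k)]
        h = ol.build_hasse(chain, include_bounds=True)
        # top == largest chain set (bounds are added only when absent)
        assert h.n_nodes == k + 1 and len(h.edges) == k

    def test_duplicates_collapse_with_combined_support(self, abc_universe):
        u = abc_universe
        recs = [
            ol.SampleRecord("H41:0", "H41", 0, u.set_of("ab")),
            ol.SampleRecord("H43:0", "H43", 0, u.set_of("ab")),
            ol.SampleRecord("H41:1", "H41", 1, u.set_of("a")),
        ]
        table = ol.MeasurementTable(u, recs)
        h = ol.build_hasse(table.taxa_sets(), table=table)
        node = next(n for n in h.nodes if n.taxa == u.set_of("ab"))
        assert set(node.support) == {"H41:0", "H43:0"}
        assert h.n_nodes == 2

    @given(st.integers(0, 10**6))
    @settings(max_examples=30)
    def test_edges_equal_brute_covering_relation(self, seed):
        sets, _ = random_sets(seed, 15)
        h = ol.build_hasse(sets)
        ds = [n.taxa for n in h.nodes]
        expect = brute_cover_edges([frozenset(s.labels()) for s in ds])
        got = sorted(
            (u_, v_) for u_, v_ in h.edges
        )
        assert got == expect

    @given(st.integers(0, 10**6))
    @settings(max_examples=20)
    def test_reachability_iff_subset(self, seed):
        sets, _ = random_sets(seed, 12)
        h = ol.build_hasse(sets)
        succs = h.successors()

        def reach(a, b):
            stack, seen = [a], set()
            while stack:
                x = stack.pop()
                if x == b:
                    return True
                if x in seen:
                    continue
                seen.add(x)
                stack.extend(succs[x])
            return False

        for n1 in h.nodes:
            for n2 in h.nodes:
                if n1.node_id == n2.node_id:
                    continue
                assert reach(n1.node_id, n2.node_id) == (n1.taxa < n2.taxa)

    @given(st.integers(0, 10**6))
    @settings(max_examples=20)
    def test_introduced_taxa_definition(self, seed):
        sets, u = random_sets(seed, 12)
        h = ol.build_hasse(sets)
        for n in h.nodes:
            below = u.empty()
            for m in h.nodes:
                if m.taxa < n.taxa:
                    below = below | m.taxa
            assert n.introduced == n.taxa - below


class TestConnectivity:
    def test_counts_small_example(self, abc_universe):
        u = abc_universe
        rep = ol.connectivity_counts([u.set_of("a"), u.set_of("ab"), u.set_of("ac")])
        got = dict(zip([s.labels() for s in rep.sets], rep.counts))
        assert got == {("a",): (0, 2), ("a", "b"): (1, 0), ("a", "c"): (1, 0)}
        assert rep.frac_connected == 1.0

    def test_antichain_fractions_zero(self, abc_universe):
        u = abc_universe
        rep = ol.connectivity_counts([u.set_of("ab"), u.set_of("cx")])
        assert rep.counts == ((0, 0), (0, 0))
        assert rep.frac_connected == 0.0


class TestPathHistogram:
    def test_diamond(self, abc_universe):
        u = abc_universe
        h = ol.build_hasse([u.set_of("a"), u.set_of("b")], include_bounds=True)
        assert ol.path_histogram(h).counts == {2: 2}

    def test_mixed_lengths(self, abc_universe):
        u = abc_universe
        h = ol.build_hasse(
            [u.set_of("a"), u.set_of("ab"), u.set_of("c")], include_bounds=True
        )
        assert ol.path_histogram(h).counts == {2: 1, 3: 1}

    @pytest.mark.parametrize("k", [1, 3, 6])
    def test_chain_single_path(self, k):
        u = universe10()
        chain = [u.set_of(list(range(1, i + 2))) for i in range(k)]
        h = ol.build_hasse(chain, include_bounds=True)
        hist = ol.path_histogram(h)
        # bottom -> c1 -> ... -> ck (= top, the union of the chain)
        assert hist.counts == {k: 1}

    def test_missing_bounds_rejected(self, abc_universe):
        u = abc_universe
        h = ol.build_hasse([u.set_of("a"), u.set_of("b")])
        with pytest.raises(ValidationError):
            ol.path_histogram(h)

    def test_capacity_guard(self, abc_universe):
        u = abc_universe
        h = ol.build_hasse([u.set_of("a"), u.set_of("b")], include_bounds=True)
        with pytest.raises(CapacityError):
            ol.path_histogram(h, max_paths=1)
        with pytest.raises(CapacityError):
            ol.enumerate_paths(h, max_paths=1)

    @given(st.integers(0, 10**6))
    @settings(max_examples=30)
    def test_dp_count_equals_dfs_enumeration(self, seed):
        sets, _ = random_sets(seed, 10)
        h = ol.build_hasse(sets, include_bounds=True)
        hist = ol.path_histogram(h)
        paths = ol.enumerate_paths(h)
        assert hist.total_paths == len(paths)
        lengths = sorted(len(p) - 1 for p in paths)
        expect = brute_paths(
            list(h.edges), h.bottom().node_id, h.top().node_id
        )
        assert lengths == expect
        got_hist = {}
        for ln in lengths:
            got_hist[ln] = got_hist.get(ln, 0) + 1
        assert got_hist == hist.counts


class TestEgoView:
    def test_focal_with_one_subset(self, abc_universe):
        u = abc_universe
        sets = [u.set_of("a"), u.set_of("ab"), u.set_of("ac")]
        h = ol.build_hasse(sets)
        focal = next(n for n in h.nodes if n.taxa == u.set_of("ab"))
        sub = ol.ego_view(h, focal.node_id)
        assert {n.taxa.labels() for n in sub.nodes} == {("a",), ("a", "b")}

    def test_isolated_focal_keeps_only_itself(self, abc_universe):
        u = abc_universe
        sets = [u.set_of("ab"), u.set_of("cx"), u.set_of("ay")]
        h = ol.build_hasse(sets)
        focal = next(n for n in h.nodes if n.taxa == u.set_of("cx"))
        sub = ol.ego_view(h, focal.node_id)
        assert [n.taxa.labels() for n in sub.nodes] == [("c", "x")]

    def test_unknown_node_rejected(self, abc_universe):
        h = ol.build_hasse([abc_universe.set_of("a")])
        with pytest.raises(ValidationError):
            ol.ego_view(h, 999)

    @given(st.integers(0, 10**6))
    @settings(max_examples=30)
    def test_membership_matches_brute_scan(self, seed):
        sets, _ = random_sets(seed, 15)
        h = ol.build_hasse(sets)
        focal = h.nodes[seed % len(h.nodes)]
        sub = ol.ego_view(h, focal.node_id)
        expect = {focal.node_id} | {
            n.node_id
            for n in h.nodes
            if n.taxa != focal.taxa
            and (n.taxa < focal.taxa or focal.taxa < n.taxa)
        }
        assert {n.node_id for n in sub.nodes} == expect
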