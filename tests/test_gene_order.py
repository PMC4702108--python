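"""Adjacency algebra, breakpoint distances and shared derived clusters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_breakpoints, random_signed_order
from mitoarch import fixtures as fx
from mitoarch.gene_order import (GeneOrder, adjacency_set, breakpoint_distance,
                                 contains_run, derived_adjacencies,
                                 read_arrangements, shared_derived_clusters,
                                 write_arrangements)
from mitoarch.synth import evolve_order

TOY = GeneOrder("toy", (("a", 1), ("b", 1), ("c", 1)))


class TestAdjacencySets:
    def test_signed_circular_toy_has_three_pairs(self):
        pairs = adjacency_set(TOY, "signed-circular").pairs
        assert len(pairs) == 3

    def test_reverse_complement_has_identical_sets(self):
        for conv in ("signed-circular", "unsigned-linear-cox1"):
            order = GeneOrder("t", (("cox1", 1), ("a", 1), ("b", -1), ("c", 1)))
            assert (adjacency_set(order, conv).pairs
                    == adjacency_set(order.reverse_complement(), conv).pairs)

    def test_unsigned_linear_counts(self, pt_order):
        s = adjacency_set(pt_order, "unsigned-linear-cox1")
        assert len(s.pairs) == 36
        assert frozenset(("trnS1", "trnI")) in s.pairs
        assert frozenset(("trnY", "trnQ")) in s.pairs

    def test_unsigned_requires_cox1(self):
        with pytest.raises(ValueError, match="cox1"):
            adjacency_set(TOY, "unsigned-linear-cox1")

    def test_cr_never_participates(self, pt_order):
        for conv in ("signed-circular", "unsigned-linear-cox1"):
            for pair in adjacency_set(pt_order, conv).pairs:
                flat = {x for p in ((pair,) if conv.startswith("unsigned") else pair)
                        for x in (p if isinstance(p, frozenset) else (p[0],))}
                assert "CR" not in flat


class TestBreakpointDistance:
    def test_published_distances_to_arthropod_ancestor(self, pt_order, es_order,
                                                       ancestor, arrangements):
        assert breakpoint_distance(pt_order, ancestor) == 13
        assert breakpoint_distance(es_order, ancestor) == 16
        assert breakpoint_distance(arrangements["Argasidae"], ancestor) == 0

    def test_identity_is_zero(self):
        rng = np.random.default_rng(11)
        for n in (4, 7, 10):
            order = random_signed_order(rng, n)
            assert breakpoint_distance(order, order) == 0

    def test_rotation_and_reflection_invariance(self, pt_order, ancestor):
        d = breakpoint_distance(pt_order, ancestor)
        assert breakpoint_distance(pt_order.rotated(11), ancestor) == d
        assert breakpoint_distance(pt_order.reverse_complement(), ancestor) == d
        assert breakpoint_distance(pt_order, ancestor.reverse_complement().rotated(5)) == d

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(3, 11))
            a = random_signed_order(rng, n, "a")
            b = random_signed_order(rng, n, "b")
            assert breakpoint_distance(a, b) == brute_breakpoints(a, b)

    def test_single_gene_move_on_six_gene_circle(self):
        # moving one gene creates three new junctions (two at the landing
        # site, one where the donor gap closed); enumerated by hand
        ref = GeneOrder("r", tuple((g, 1) for g in "abcdef"))
        tgt = GeneOrder("t", tuple((g, 1) for g in "abdecf"))  # c moved between e and f
        assert breakpoint_distance(tgt, ref) == 3
        assert brute_breakpoints(tgt, ref) == 3

    def test_gene_set_mismatch_lists_difference(self):
        other = GeneOrder("o", (("a", 1), ("b", 1), ("d", 1)))
        with pytest.raises(ValueError, match="'c'"):
            breakpoint_distance(TOY, other)

    def test_mean_distance_monotone_in_event_count(self, ancestor):
        rng = np.random.default_rng(5)
        base = random_signed_order(rng, 10, "root")
        means = []
        for k in range(0, 11):
            dists = []
            for rep in range(100):
                evolved, _ = evolve_order(base, k, rng_seed=1000 * k + rep)
                dists.append(breakpoint_distance(evolved, base))
            means.append(float(np.mean(dists)))
        assert means[0] == 0.0
        assert all(b >= a - 0.5 for a, b in zip(means, means[1:]))
        assert means[-1] > means[1]


@st.composite
def signed_orders(draw, n_min=3, n_max=9):
    n = draw(st.integers(n_min, n_max))
    perm = draw(st.permutations(range(n)))
    signs = draw(st.lists(st.sampled_from([1, -1]), min_size=n, max_size=n))
    return GeneOrder("h", tuple((f"g{i}", s) for i, s in zip(perm, signs)))


class TestProperties:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(signed_orders())
    def test_identity_distance_zero_and_symmetry_with_oracle(self, order):
        assert breakpoint_distance(order, order) == 0
        assert breakpoint_distance(order, order.reverse_complement()) == 0

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(signed_orders(), st.integers(0, 20))
    def test_rotation_invariance_against_brute_force(self, order, k):
        rotated = order.rotated(k)
        ref = GeneOrder("ref", tuple((f"g{i}", 1) for i in range(len(order))))
        d = breakpoint_distance(order, ref)
        assert breakpoint_distance(rotated, ref) == d
        assert d == brute_breakpoints(order, ref)


class TestDerivedAdjacencies:
    def test_identical_orders_share_everything(self, ancestor):
        assert len(derived_adjacencies(ancestor, ancestor).pairs) == 0

    def test_pt_unsigned_derived_content(self, pt_order, ancestor):
        pairs = derived_adjacencies(pt_order, ancestor, "unsigned-linear-cox1").pairs
        assert frozenset(("trnY", "trnQ")) in pairs
        assert frozenset(("nad6", "trnT")) in pairs
        # nad2-trnW is ancestral (order only flipped), so not derived unsigned
        assert frozenset(("trnW", "nad2")) not in pairs

    def test_cardinality_equals_distance(self, pt_order, es_order, ancestor):
        for t in (pt_order, es_order):
            for conv in ("signed-circular", "unsigned-linear-cox1"):
                assert len(derived_adjacencies(t, ancestor, conv).pairs) \
                    == breakpoint_distance(t, ancestor, conv)


class TestSharedDerivedClusters:
    PAPER_CLUSTERS = {"trnS1-trnI-trnE", "nad6-trnT-cob",
                      "trnY-trnQ-rrnS-trnV-rrnL", "trnW-nad2-trnM-trnC"}

    def test_target_identical_to_reference_yields_nothing(self, ancestor):
        assert shared_derived_clusters([ancestor], ancestor) == []

    def test_unscreened_run_content(self, pt_order, es_order, ancestor):
        labels = {c.label for c in shared_derived_clusters([pt_order, es_order], ancestor)}
        assert "trnS1-trnI-trnE" in labels
        assert "nad6-trnT-cob" in labels

    def test_screen_leaves_exactly_the_four_eriophyoid_clusters(
            self, pt_order, es_order, ancestor, screen_orders):
        found = shared_derived_clusters([pt_order, es_order], ancestor, screen_orders)
        assert {c.label for c in found} == self.PAPER_CLUSTERS

    def test_inverted_block_chains_as_one_run(self, pt_order, es_order, ancestor,
                                              screen_orders):
        # the relocated-and-inverted rrnS-trnV-rrnL block must chain with
        # trnY-trnQ into a single five-gene run
        found = shared_derived_clusters([pt_order, es_order], ancestor, screen_orders)
        big = max(found, key=lambda c: len(c.genes))
        assert [g for g, _ in big.genes] == ["trnY", "trnQ", "rrnS", "trnV", "rrnL"]
        assert all(s == 1 for _, s in big.genes)

    def test_cr_interrupts_a_run(self, pt_order, es_order, ancestor):
        # rrnL-trnW are in contact in Es but separated by the CR in Pt, so
        # the pair cannot be a shared run member
        for c in shared_derived_clusters([pt_order, es_order], ancestor):
            names = [g for g, _ in c.genes]
            assert not ("rrnL" in names and "trnW" in names)


class TestContainsRun:
    def test_cluster_runs_present_in_both_eriophyoids(self, pt_order, es_order):
        run = (("trnS1", 1), ("trnI", 1), ("trnE", 1))
        assert contains_run(pt_order, run) and contains_run(es_order, run)

    def test_run_absent_from_ancestor(self, ancestor):
        assert not contains_run(ancestor, (("trnS1", 1), ("trnI", 1), ("trnE", 1)))

    def test_reverse_reading_detected(self, pt_order):
        run = (("trnE", -1), ("trnI", -1), ("trnS1", -1))
        assert contains_run(pt_order, run)


class TestExchangeFormat:
    def test_round_trip(self, arrangements):
        text = write_arrangements(arrangements.values(), header="panel")
        again = read_arrangements(text)
        assert set(again) == set(arrangements)
        for name in arrangements:
            assert again[name].genes == arrangements[name].genes
            assert again[name].cr_after == arrangements[name].cr_after

    def test_duplicate_taxon_rejected(self):
        text = "a\tcox1 cox2\na\tcox1 cox2\n"
        with pytest.raises(ValueError, match="duplicate"):
            read_arrangements(text)
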