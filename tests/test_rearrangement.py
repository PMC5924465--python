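"""Breakpoint distances and synteny blocks on circular gene orders,
cross-checked against a brute-force adjacency oracle."""

import itertools

import pytest
from hypothesis import given, strategies as st

from ctenomito.io import AnnotationSet, GeneFeature
from ctenomito.rearrange import (
    GeneOrder,
    breakpoint_distance,
    distance_matrix,
    gene_order_from_annotation,
    render_distance_table,
    restrict_to_shared,
    round_display,
    synteny_blocks,
)
from ctenomito.simulate import rearrange_order


def oracle_bd(a: tuple, b: tuple) -> int:
    """Brute force: enumerate directed circular adjacencies and count misses."""
    adj_a = []
    for i in range(len(a)):
        adj_a.append((a[i], a[(i + 1) % len(a)]))
    adj_b = []
    for i in range(len(b)):
        adj_b.append((b[i], b[(i + 1) % len(b)]))
    return sum(1 for x in adj_a if x not in adj_b)


perm = st.integers(2, 8).flatmap(
    lambda n: st.permutations([f"g{i}" for i in range(n)]).flatmap(
        lambda p1: st.permutations([f"g{i}" for i in range(n)]).map(lambda p2: (tuple(p1), tuple(p2)))
    )
)


class TestBreakpointDistance:
    def test_identical_orders_zero(self):
        a = GeneOrder("a", ("cox1", "cox2", "cob"))
        assert breakpoint_distance(a, GeneOrder("b", a.order)).bd == 0

    def test_worked_example(self):
        a = GeneOrder("a", tuple("12345"))
        b = GeneOrder("b", ("1", "3", "2", "4", "5"))
        res = breakpoint_distance(a, b)
        # adjacency sets {12,23,34,45,51} vs {13,32,24,45,51}: intersection {45,51}
        assert res.bd == 3 and res.n_shared == 5

    def test_display_rounding_matches_published_convention(self):
        from ctenomito.rearrange import BreakpointResult

        assert BreakpointResult(9, 13).bdn_display == 0.69
        assert BreakpointResult(11, 13).bdn_display == 0.85
        assert BreakpointResult(12, 13).bdn_display == 0.92
        assert BreakpointResult(5, 13).bdn_display == 0.38

    def test_label_set_mismatch_raises(self):
        a = GeneOrder("a", ("x", "y"))
        b = GeneOrder("b", ("x", "z"))
        with pytest.raises(ValueError):
            breakpoint_distance(a, b)

    @given(perm)
    def test_equals_brute_force_oracle(self, pair):
        p1, p2 = pair
        res = breakpoint_distance(GeneOrder("a", p1), GeneOrder("b", p2))
        assert res.bd == oracle_bd(p1, p2)
        assert res.bd == oracle_bd(p2, p1)  # symmetry

    @given(perm, st.integers(0, 7), st.integers(0, 7))
    def test_rotation_invariance(self, pair, r1, r2):
        p1, p2 = pair
        a, b = GeneOrder("a", p1), GeneOrder("b", p2)
        base = breakpoint_distance(a, b).bd
        assert breakpoint_distance(a.rotated(r1), b.rotated(r2)).bd == base

    def test_bdn_one_attainable(self):
        a = GeneOrder("a", tuple("1234"))
        b = GeneOrder("b", tuple(reversed("1234")))  # directed: all broken
        assert breakpoint_distance(a, b).bdn == 1.0


class TestSynteny:
    def test_full_conservation_single_circular_block(self):
        a = GeneOrder("a", tuple("12345"))
        blocks = synteny_blocks(a, GeneOrder("b", a.order))
        assert len(blocks) == 1 and blocks[0].circular and blocks[0].length == 5

    def test_worked_example_merged_circularly(self):
        a = GeneOrder("a", tuple("12345"))
        b = GeneOrder("b", ("1", "2", "4", "3", "5"))
        blocks = synteny_blocks(a, b)
        assert [bl.genes for bl in blocks] == [("5", "1", "2")]

    def test_full_reversal_no_blocks(self):
        a = GeneOrder("a", tuple("12345"))
        b = GeneOrder("b", tuple(reversed("12345")))
        assert synteny_blocks(a, b) == []

    @given(perm)
    def test_blocks_account_for_exactly_conserved_adjacencies(self, pair):
        p1, p2 = pair
        a, b = GeneOrder("a", p1), GeneOrder("b", p2)
        res = breakpoint_distance(a, b)
        blocks = synteny_blocks(a, b)
        assert sum(bl.n_adjacencies for bl in blocks) == res.n_shared - res.bd

    @given(perm, st.integers(0, 7))
    def test_blocks_rotation_invariant(self, pair, r):
        p1, p2 = pair
        a, b = GeneOrder("a", p1), GeneOrder("b", p2)
        s1 = {bl.genes for bl in synteny_blocks(a, b)}
        s2 = {bl.genes for bl in synteny_blocks(a.rotated(r), b)}
        assert s1 == s2


class TestRestrictAndOrders:
    def test_restriction_example(self):
        a = GeneOrder("a", ("x", "y", "z", "w"))
        b = GeneOrder("b", ("x", "z", "y"))
        ra, rb = restrict_to_shared(a, b)
        assert ra.order == ("x", "y", "z") and rb.order == ("x", "z", "y")

    def test_identical_sets_unchanged(self):
        a = GeneOrder("a", ("x", "y"))
        b = GeneOrder("b", ("y", "x"))
        ra, rb = restrict_to_shared(a, b)
        assert ra.order == a.order and rb.order == b.order

    @given(perm, st.integers(0, 7))
    def test_restriction_commutes_with_rotation(self, pair, r):
        p1, p2 = pair
        a, b = GeneOrder("a", p1 + ("extraA",)), GeneOrder("b", p2 + ("extraB",))
        ra, _ = restrict_to_shared(a, b)
        ra_rot, _ = restrict_to_shared(a.rotated(r), b)
        assert ra == ra_rot  # GeneOrder equality is rotation-invariant

    def test_gene_order_from_annotation(self):
        ann = AnnotationSet(
            "g",
            [
                GeneFeature("cox1", 10, 100),
                GeneFeature("urf1", 700, 810, kind="URF"),
                GeneFeature("cox2", 500, 600),
                GeneFeature("cob", 900, 980),
            ],
        )
        assert gene_order_from_annotation(ann).order == ("cox1", "cox2", "cob")
        assert gene_order_from_annotation(ann, include_urfs=True).order == (
            "cox1", "cox2", "urf1", "cob",
        )


class TestMatrix:
    def test_symmetric_zero_diagonal(self):
        orders = [
            GeneOrder("a", tuple("12345")),
            GeneOrder("b", ("1", "3", "2", "4", "5")),
            GeneOrder("c", tuple("13254")),
        ]
        mat = distance_matrix(orders)
        for i in range(3):
            assert mat.iloc[i, i] is None
            for j in range(3):
                if i != j:
                    assert mat.iloc[i, j].bd == mat.iloc[j, i].bd

    def test_generator_ledger_distances_bounded(self):
        base = GeneOrder("x", tuple(f"g{i}" for i in range(13)))
        for k in (0, 1, 2, 4):
            moved, ledger = rearrange_order(base, k, seed=k + 1)
            bd = breakpoint_distance(base, GeneOrder("x", moved.order)).bd
            assert bd <= 3 * k
            assert len(ledger.rearrangement_moves) == k
            if k == 0:
                assert bd == 0

    def test_single_transposition_bd_in_2_3(self):
        base = GeneOrder("x", tuple(f"g{i}" for i in range(13)))
        seen = set()
        for s in range(40):
            moved, _ = rearrange_order(base, 1, seed=s)
            seen.add(breakpoint_distance(base, GeneOrder("x", moved.order)).bd)
        assert seen <= {2, 3}

    def test_rendered_table_shape(self):
        orders = [GeneOrder("a", tuple("1234")), GeneOrder("b", tuple("1324"))]
        mat = distance_matrix(orders)
        text = render_distance_table(mat)
        lines = text.splitlines()
        assert len(lines) == 3
        # BD (integer) above the diagonal, BDn (2 decimals) below
        assert lines[1].split()[-1].isdigit()
        assert "." in lines[2].split()[1]


def test_round_display_half_up():
    assert round_display(0.125, 2) == 0.13
    assert round_display(9 / 13, 2) == 0.69
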