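import random
from itertools import permutations, product

import pytest

from sheetfold.blueprint import mock_coordinates
from sheetfold.rules import (
    ANTI,
    ENDING_RULE,
    JUMP_RULE,
    OVERLAP_RULE,
    PARA,
    check_ending_rule,
    check_jump_rule,
    check_overlap_rule,
    classification_counts,
    classify_all,
    classify_topology,
    connection_face,
    connections_of,
    ending_side,
    greek_key_exempt,
)
from sheetfold.topology import (
    SheetTopology,
    enumerate_topologies,
    expected_count,
    parse_topology,
    symmetry_images,
)


def rules_violated(t):
    return {v.rule for v in classify_topology(t).violations}


class TestConnections:
    def test_meander_is_three_hairpins(self, meander):
        cons = connections_of(meander)
        assert [c.kind for c in cons] == [ANTI] * 3
        assert [c.jump for c in cons] == [0, 0, 0]
        assert all(c.face is None for c in cons)

    def test_1342_uddd_connections(self):
        cons = connections_of(parse_topology("1342:uddd"))
        assert [(c.kind, c.jump) for c in cons] == [(ANTI, 2), (PARA, 1), (PARA, 0)]
        assert cons[0].span == (1, 4)

    def test_knot_all_para(self, knot):
        cons = connections_of(knot)
        assert [(c.kind, c.jump) for c in cons] == [(PARA, 1), (PARA, 2), (PARA, 1)]

    def test_connection_count_always_n_minus_1(self):
        for t in enumerate_topologies(5)[::97]:
            assert len(connections_of(t)) == t.n - 1


class TestFaces:
    def test_para_opposite_travel_opposite_faces(self):
        left = connection_face(PARA, 0, -1, "u")
        right = connection_face(PARA, 0, +1, "u")
        assert {left, right} == {"front", "back"} and left != right

    def test_hairpin_has_no_face(self):
        assert connection_face(ANTI, 0, 1, "u") is None

    def test_ending_side_of_anti_is_none(self):
        assert ending_side(ANTI, 1, "u") is None

    def test_ending_side_equals_arrival_face_for_para(self):
        for d, o in product((1, -1), "ud"):
            assert ending_side(PARA, d, o) == connection_face(PARA, 1, d, o)

    def test_position_reversal_flips_every_face(self):
        # the rotation that reverses positions but keeps orientations turns
        # the sheet over: every non-hairpin connection changes face
        t = parse_topology("3142:uuuu")
        rev = SheetTopology(tuple(reversed(t.order)), tuple(reversed(t.orient)))
        for a, b in zip(connections_of(t), connections_of(rev)):
            assert a.face != b.face

    def test_global_orientation_flip_preserves_verdicts(self):
        """Flipping every strand flips every face label (the global
        front/back convention) but must not change any S/D verdict."""
        for t in enumerate_topologies(4):
            flipped = SheetTopology(
                t.order, tuple("u" if c == "d" else "d" for c in t.orient)
            )
            assert classify_topology(t).violations == classify_topology(flipped).violations


class TestGreekKeyExemption:
    def test_greek_key_third_connection_exempt(self, greek_key):
        cons = connections_of(greek_key)
        assert cons[2].kind == ANTI and cons[2].jump == 2
        assert greek_key_exempt(cons[2], greek_key)

    @pytest.mark.parametrize("text,conn", [("3412:dudu", 2), ("2341:dudu", 1)])
    def test_circular_permutants_exempt(self, text, conn):
        t = parse_topology(text)
        assert greek_key_exempt(connections_of(t)[conn - 1], t)

    def test_non_alternating_window_not_exempt(self):
        t = parse_topology("1342:uddd")
        assert not greek_key_exempt(connections_of(t)[0], t)

    def test_para_connection_never_exempt(self, knot):
        c = connections_of(knot)[1]  # para, jump 2
        assert c.jump == 2 and not greek_key_exempt(c, knot)

    def test_embedded_window_recognized_at_n5(self):
        # Greek key over strands 1-4 occupying positions 2..5 of a
        # five-stranded sheet (strand 5 hairpinned onto the left edge)
        t = parse_topology("54123:ududu")
        long_jumps = [
            c
            for c in connections_of(t)
            if c.kind == ANTI and c.jump == 2
        ]
        assert any(greek_key_exempt(c, t) for c in long_jumps)


class TestRuleChecks:
    def test_meander_clean(self, meander):
        assert classify_topology(meander).frustration_free

    def test_1342_uddd_jump_and_overlap_only(self):
        t = parse_topology("1342:uddd")
        assert [v.connections for v in check_jump_rule(t)] == [(1,)]
        overlaps = check_overlap_rule(t)
        assert overlaps and all(1 in v.connections for v in overlaps)
        assert check_ending_rule(t) == []
        assert not classify_topology(t).frustration_free

    def test_knot_frustration_free(self, knot):
        assert classify_topology(knot).frustration_free

    def test_greek_key_family_frustration_free(self):
        for text in ("4123:dudu", "3412:dudu", "2341:dudu"):
            assert classify_topology(parse_topology(text)).frustration_free

    def test_all_parallel_divergent_endings_frustrated(self):
        # two parallel motifs ending on adjacent parallel strands from
        # opposite travel directions: D-type ending violation
        t = parse_topology("1243:uuuu")
        assert rules_violated(t) == {ENDING_RULE}

    def test_long_para_jump_at_n6(self):
        # parallel connection skipping four strands violates the jump rule
        t = parse_topology("461235:uuuuuu")
        cons = connections_of(t)
        assert any(c.kind == PARA and c.jump >= 4 for c in cons)
        assert JUMP_RULE in rules_violated(t)


class TestClassifyAll:
    @pytest.mark.parametrize(
        "n,free,frustrated", [(3, 10, 2), (4, 43, 53)]
    )
    def test_printed_counts(self, n, free, frustrated):
        assert classification_counts(n) == (free, frustrated)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_conservation(self, n):
        free, frustrated = classification_counts(n)
        assert free + frustrated == expected_count(n)

    def test_verdicts_invariant_under_symmetry_exhaustive_n4(self):
        for t in enumerate_topologies(4):
            verdicts = {
                classify_topology(i).frustration_free for i in symmetry_images(t)
            }
            assert len(verdicts) == 1

    def test_verdicts_invariant_under_symmetry_sampled_n5_n6(self):
        rng = random.Random(20240131)
        for n in (5, 6):
            sample = rng.sample(enumerate_topologies(n), 120)
            for t in sample:
                verdicts = {
                    classify_topology(i).frustration_free
                    for i in symmetry_images(t)
                }
                assert len(verdicts) == 1

    def test_stream_matches_counts(self):
        frees = sum(c.frustration_free for c in classify_all(4))
        assert frees == classification_counts(4)[0]


class TestGeometricOracle:
    def test_mock_routing_reproduces_para_faces_n3_n4(self):
        """The mock-coordinate router picks the crossover face by screw
        sense alone; it must agree with the analytic face for every parallel
        connection of every 3- and 4-stranded topology."""
        for n in (3, 4):
            for t in enumerate_topologies(n):
                mock = mock_coordinates(t)
                for conn, face in zip(connections_of(t), mock.connector_faces):
                    if conn.kind == PARA:
                        assert conn.face == face

    def test_mock_bend_edges_match_strand_orientation(self):
        t = parse_topology("1342:uddd")
        mock = mock_coordinates(t)
        cons = connections_of(t)
        # the jump-2 bend leaves the top of the up-pointing first strand
        assert cons[0].kind == ANTI and mock.connector_edges[0] == "top"
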