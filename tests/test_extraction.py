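import warnings

import networkx as nx
import pytest

from conftest import write_ladder_pdb
from sheetfold.blueprint import mock_coordinates
from sheetfold.extraction import (
    ExtractionError,
    StrandSegment,
    assemble_sheets,
    build_pairing_graph,
    detect_strands,
    extract_topologies,
    parse_structure,
    sheet_to_topology,
    strands_from_ranges,
)
from sheetfold.topology import canonicalize, format_topology, parse_topology


def mock_pdb(tmp_path, text, strand_length=5):
    t = parse_topology(text)
    m = mock_coordinates(t, strand_length)
    path = tmp_path / "mock.pdb"
    m.to_pdb(path)
    return path, m, t


def extract_quiet(path, ranges):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return extract_topologies(path, ranges)


class TestParseStructure:
    def test_mock_model(self, tmp_path):
        path, m, _ = mock_pdb(tmp_path, "1234:udud")
        with pytest.warns(UserWarning, match="Cα-only"):
            model = parse_structure(path)
        assert model.ca_only
        assert len(model.atoms) == m.n_residues

    def test_backbone_model_not_ca_only(self, tmp_path):
        path = write_ladder_pdb(tmp_path / "ladder.pdb")
        model = parse_structure(path)
        assert not model.ca_only

    def test_multi_model_uses_first(self, tmp_path):
        path, _, _ = mock_pdb(tmp_path, "1234:udud")
        text = path.read_text().replace("END", "")
        two = "MODEL     1\n" + text + "ENDMDL\nMODEL     2\n" + text + "ENDMDL\nEND\n"
        p2 = tmp_path / "two.pdb"
        p2.write_text(two)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = parse_structure(p2)
        assert len({c for c, _ in model.atoms}) == 1

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(ExtractionError, match="Cα"):
            parse_structure(p)


class TestPairing:
    def test_ladder_hbonds_make_one_anti_edge(self, tmp_path):
        path = write_ladder_pdb(tmp_path / "l.pdb", n_pairs=4)
        model = parse_structure(path)
        g = build_pairing_graph(model)
        assert len(g.edges) == 1
        (_, _, data), = g.edges(data=True)
        assert data["n_bonds"] >= 2 and data["relation"] == "anti"

    def test_single_hbond_insufficient(self, tmp_path):
        path = write_ladder_pdb(tmp_path / "l.pdb", n_pairs=4, bonds=1)
        model = parse_structure(path)
        strands = strands_from_ranges(model, [("A", 1, 4), ("A", 11, 14)])
        g = build_pairing_graph(model, strands)
        assert len(g.edges) == 0

    def test_short_strand_dropped(self, tmp_path):
        path = write_ladder_pdb(tmp_path / "l.pdb", n_pairs=4)
        model = parse_structure(path)
        strands = strands_from_ranges(model, [("A", 1, 2), ("A", 11, 14)])
        assert [s.length for s in strands] == [4]

    def test_detected_strands_match_construction(self, tmp_path):
        path = write_ladder_pdb(tmp_path / "l.pdb", n_pairs=4)
        segs = detect_strands(parse_structure(path))
        assert [(s.start, s.end) for s in sorted(segs, key=lambda s: s.start)] == [
            (1, 4),
            (11, 14),
        ]


def seg(start, end, chain="A"):
    return StrandSegment(chain, start, end, (0.0, 1.0, 0.0))


def path_graph(*segments):
    g = nx.Graph()
    g.add_nodes_from(segments)
    for a, b in zip(segments[:-1], segments[1:]):
        g.add_edge(a, b, n_bonds=3, relation="anti")
    return g


class TestAssembleSheets:
    def test_four_strand_path_is_one_sheet(self):
        g = path_graph(seg(1, 5), seg(10, 14), seg(20, 24), seg(30, 34))
        sheets = assemble_sheets(g)
        assert len(sheets) == 1 and len(sheets[0]) == 4

    def test_branch_discarded(self):
        hub = seg(10, 14)
        g = nx.Graph()
        for leaf in (seg(1, 5), seg(20, 24), seg(30, 34)):
            g.add_edge(hub, leaf, n_bonds=3, relation="anti")
        assert assemble_sheets(g) == []

    def test_cycle_discarded(self):
        nodes = [seg(1, 5), seg(10, 14), seg(20, 24), seg(30, 34)]
        g = path_graph(*nodes)
        g.add_edge(nodes[-1], nodes[0], n_bonds=3, relation="anti")
        assert assemble_sheets(g) == []

    def test_two_strand_component_ignored(self):
        g = path_graph(seg(1, 5), seg(10, 14))
        assert assemble_sheets(g) == []

    def test_interleaved_sheets_discarded(self):
        # sheet 2 inserts a strand (6-8) into sheet 1's sequence gap (and the
        # interleaving is necessarily mutual), so neither sheet qualifies
        s1 = [seg(1, 5), seg(10, 14), seg(20, 24)]
        s2 = [seg(6, 8), seg(30, 34), seg(40, 44)]
        g = nx.Graph()
        for sheet in (s1, s2):
            for a, b in zip(sheet[:-1], sheet[1:]):
                g.add_edge(a, b, n_bonds=3, relation="anti")
        assert assemble_sheets(g) == []

    def test_separate_sheets_both_kept(self):
        s1 = [seg(1, 5), seg(10, 14), seg(20, 24)]
        s2 = [seg(30, 34), seg(40, 44), seg(50, 54)]
        g = nx.Graph()
        for sheet in (s1, s2):
            for a, b in zip(sheet[:-1], sheet[1:]):
                g.add_edge(a, b, n_bonds=3, relation="anti")
        assert len(assemble_sheets(g)) == 2


class TestSheetToTopology:
    def test_meander_round_trip(self, tmp_path):
        path, m, t = mock_pdb(tmp_path, "1234:udud")
        got = extract_quiet(path, [("A", a, b) for a, b in m.strand_ranges])
        assert got == [t]

    def test_knot_round_trip_canonical(self, tmp_path):
        path, m, t = mock_pdb(tmp_path, "3142:uuuu")
        got = extract_quiet(path, [("A", a, b) for a, b in m.strand_ranges])
        assert got == [canonicalize(t)]

    def test_reversed_path_same_topology(self, tmp_path):
        path, m, t = mock_pdb(tmp_path, "2134:uddu")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = parse_structure(path)
        strands = strands_from_ranges(model, [("A", a, b) for a, b in m.strand_ranges])
        g = build_pairing_graph(model, strands)
        (sheet,) = assemble_sheets(g)
        assert sheet_to_topology(sheet, g) == sheet_to_topology(sheet[::-1], g)

    def test_multichain_sheet_rejected(self):
        a, b, c = seg(1, 5), seg(10, 14), seg(20, 24, chain="B")
        g = path_graph(a, b, c)
        with pytest.raises(ExtractionError, match="chains"):
            sheet_to_topology([a, b, c], g)
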