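"""Design blueprints and idealized mock geometry for sheet topologies.

A blueprint is the per-residue specification used to constrain backbone
generation in de novo design: secondary structure (H/E/L) plus an ABEGO
torsion letter per residue (A: α region, B: β region, G/E: positive-φ
regions, O: cis-peptide).  Strands are joined according to their connection
type: a parallel connection expands to loop–helix–loop (the X region of a
parallel β-X-β motif is an α-helix), an antiparallel jump-0 connection to a
two-strand hairpin loop, and an antiparallel long-range connection to a
helix or, optionally, an α-turn (helix–loop–helix).  Loop ABEGO patterns are
drawn from a fixed table of allowed patterns per connection-unit type.

The same module provides :func:`mock_coordinates`: idealized Cα traces of a
topology on a planar lattice with connectors routed as right-handed
polylines.  The mocks serve two purposes: they are the geometric oracle for
the face conventions of :mod:`sheetfold.rules` (the routing selects the face
by maximizing a screw-sense functional, independently of the analytic face
formula), and they are fixtures for coordinate-based topology extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np

from .rules import ANTI, BACK, FRONT, PARA, Connection, connections_of
from .topology import DOWN, UP, SheetTopology, format_topology

# ---------------------------------------------------------------------------
# Loop pattern table
# ---------------------------------------------------------------------------

#: Allowed ABEGO loop patterns per connection-unit type; the first entry of
#: each tuple is the deterministic default.
LOOP_PATTERNS: dict[str, tuple[str, ...]] = {
    "para-ab": ("GB", "GBA", "BAAB", "GABA", "BA"),  # helix → strand, parallel motif
    "para-ba": ("AB",),                               # strand → helix, parallel motif
    "anti-ab": ("GBB",),                              # helix → strand, antiparallel motif
    "anti-ba": ("BAB", "GBB", "AAAB"),                # strand → helix, antiparallel motif
    "bb-R": ("BAAGB",),                               # hairpin, right chirality
    "bb-L": ("GG",),                                  # hairpin, left chirality
    "alpha-turn": ("GBB",),                           # helix–loop–helix connector
}

STRAND_LENGTH_RANGE = (4, 7)
HELIX_LENGTH_RANGE = (11, 17)


def loop_pattern_for(unit: str) -> tuple[str, ...]:
    """Allowed ABEGO strings for a connection-unit type (default first)."""
    try:
        return LOOP_PATTERNS[unit]
    except KeyError:
        raise ValueError(
            f"unknown connection unit {unit!r}; expected one of {sorted(LOOP_PATTERNS)}"
        ) from None


# ---------------------------------------------------------------------------
# Blueprint
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlueprintConfig:
    strand_length: int = 5
    helix_length: int = 13
    terminal_helices: bool = False
    alpha_turns: bool = False          # α-turn X region for antiparallel bends
    hairpin_chirality: str = "R"       # R (BAAGB) or L (GG)
    pattern_choice: dict = field(default_factory=dict)   # unit → pattern
    residue_letter: str = "V"

    def pattern(self, unit: str) -> str:
        allowed = loop_pattern_for(unit)
        chosen = self.pattern_choice.get(unit, allowed[0])
        if chosen not in allowed:
            raise ValueError(
                f"pattern {chosen!r} not allowed for unit {unit!r} (allowed: {allowed})"
            )
        return chosen


@dataclass(frozen=True)
class BlueprintRow:
    index: int
    residue: str
    ss: str       # H / E / L
    abego: str    # single ABEGO letter


@dataclass(frozen=True)
class Blueprint:
    topology: SheetTopology
    rows: tuple[BlueprintRow, ...]
    #: (kind, length) layout summary; derived metadata, excluded from equality
    elements: tuple[tuple[str, int], ...] = field(compare=False, default=())

    def __len__(self) -> int:
        return len(self.rows)


def _check_length(kind: str, value: int, bounds: tuple[int, int]) -> None:
    lo, hi = bounds
    if not lo <= value <= hi:
        warnings.warn(
            f"{kind} length {value} outside the usual {lo}..{hi} range",
            stacklevel=3,
        )


def build_blueprint(t: SheetTopology, config: BlueprintConfig | None = None) -> Blueprint:
    """Compile a topology into a residue-level blueprint.

    Layout: strand 1, then for each connection the connector expansion, then
    the next strand; optional terminal helices are attached with parallel-
    type αβ/βα loops.  Deterministic for a fixed config.
    """
    config = config or BlueprintConfig()
    _check_length("strand", config.strand_length, STRAND_LENGTH_RANGE)
    _check_length("helix", config.helix_length, HELIX_LENGTH_RANGE)

    elements: list[tuple[str, int]] = []
    pieces: list[tuple[str, str]] = []   # (ss letter, abego letter) per residue

    def add(kind: str, ss: str, letters: str) -> None:
        elements.append((kind, len(letters)))
        pieces.extend((ss, a) for a in letters)

    def add_loop(unit: str) -> None:
        add(f"loop:{unit}", "L", config.pattern(unit))

    def add_helix() -> None:
        add("helix", "H", "A" * config.helix_length)

    def add_strand() -> None:
        add("strand", "E", "B" * config.strand_length)

    if config.terminal_helices:
        add_helix()
        add_loop("para-ab")
    add_strand()
    for c in connections_of(t):
        if c.kind == ANTI and c.jump == 0:
            add_loop("bb-R" if config.hairpin_chirality == "R" else "bb-L")
        elif c.kind == PARA:
            add_loop("para-ba")
            add_helix()
            add_loop("para-ab")
        else:  # antiparallel bend: helix X region, optionally an α-turn
            add_loop("anti-ba")
            add_helix()
            if config.alpha_turns:
                add_loop("alpha-turn")
                add_helix()
            add_loop("anti-ab")
        add_strand()
    if config.terminal_helices:
        add_loop("para-ba")
        add_helix()

    rows = tuple(
        BlueprintRow(i, config.residue_letter, ss, abego)
        for i, (ss, abego) in enumerate(pieces, start=1)
    )
    return Blueprint(t, rows, tuple(elements))


def write_blueprint(bp: Blueprint, fh: TextIO) -> None:
    """Write the blueprint dialect: ``index residue SS+ABEGO R`` per line."""
    fh.write(f"# topology {format_topology(bp.topology)}\n")
    for r in bp.rows:
        fh.write(f"{r.index}\t{r.residue}\t{r.ss}{r.abego}\tR\n")


def read_blueprint(fh: TextIO, topology: SheetTopology | None = None) -> Blueprint:
    """Read the dialect written by :func:`write_blueprint` (round-trip exact)."""
    from .topology import parse_topology

    rows = []
    topo = topology
    for line in fh:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "topology" in line and topo is None:
                topo = parse_topology(line.split()[-1])
            continue
        idx, res, ssab, _flag = line.split("\t")
        rows.append(BlueprintRow(int(idx), res, ssab[0], ssab[1:]))
    if topo is None:
        raise ValueError("blueprint file carries no topology header")
    elements: list[tuple[str, int]] = []
    for r in rows:
        kind = {"H": "helix", "E": "strand", "L": "loop"}[r.ss]
        if elements and elements[-1][0] == kind and kind != "loop":
            elements[-1] = (kind, elements[-1][1] + 1)
        elif elements and elements[-1][0] == "loop" and kind == "loop":
            elements[-1] = (kind, elements[-1][1] + 1)
        else:
            elements.append((kind, 1))
    return Blueprint(topo, tuple(rows), tuple(elements))


# ---------------------------------------------------------------------------
# Mock geometry
# ---------------------------------------------------------------------------

#: idealized lattice constants (Å)
STRAND_SPACING = 4.8   # between adjacent sheet positions
RESIDUE_RISE = 3.4     # Cα rise along a strand
CROSSOVER_LIFT = 6.0   # |z| of a parallel crossover connector
BEND_LIFT = 2.5        # |z| of an antiparallel edge bend
EDGE_CLEARANCE = 4.0   # how far beyond the strand ends connectors reach


@dataclass(frozen=True)
class MockStructure:
    topology: SheetTopology
    coords: np.ndarray                       # (n_res, 3) Cα positions
    strand_ranges: tuple[tuple[int, int], ...]   # per strand (sequence order), 1-based inclusive
    connector_faces: tuple[str | None, ...]  # per connection, FRONT/BACK/None
    connector_edges: tuple[str | None, ...]  # per connection, top/bottom/None

    @property
    def n_residues(self) -> int:
        return len(self.coords)

    def to_pdb(self, dest: str | Path) -> None:
        write_mock_pdb(self, dest)

    def write_strand_table(self, fh: TextIO) -> None:
        fh.write("chain\tstart\tend\n")
        for start, end in self.strand_ranges:
            fh.write(f"A\t{start}\t{end}\n")


def _screw_sense(path: np.ndarray, axis: np.ndarray) -> float:
    """Net circulation of ``path`` about ``axis`` through the path centroid.

    Positive values mean the path advances as a right-handed screw along
    ``axis``; used to pick the right-handed crossover face without appealing
    to the analytic face formula.
    """
    axis = axis / np.linalg.norm(axis)
    centered = path - path.mean(axis=0)
    steps = np.diff(path, axis=0)
    return float(np.einsum("ij,ij->", np.cross(centered[:-1], steps), axis[None, :]))


def _strand_trace(position: int, orient: str, length: int) -> np.ndarray:
    x = (position - 1) * STRAND_SPACING
    ys = np.arange(length) * RESIDUE_RISE
    if orient == DOWN:
        ys = ys[::-1]
    return np.column_stack([np.full(length, x), ys, np.zeros(length)])


def _connector(start: np.ndarray, end: np.ndarray, waypoints: list[np.ndarray]) -> np.ndarray:
    """Polyline of pseudo-Cα points between two strand ends (exclusive)."""
    pts = [start] + waypoints + [end]
    out = []
    for a, b in zip(pts[:-1], pts[1:]):
        seg = np.linspace(a, b, 3)[1:-1]   # one midpoint per leg
        out.append(seg)
        out.append(b[None, :])
    return np.vstack(out)[:-1]   # drop the final strand point


def mock_coordinates(
    t: SheetTopology, strand_length: int = 5
) -> MockStructure:
    """Idealized Cα model of a topology with right-handed connectors.

    Strands are straight traces on a planar lattice.  Parallel crossovers
    are routed on the face on which the strand–connector–strand path forms
    a right-handed screw (selected by :func:`_screw_sense` over both
    candidate routes).  Antiparallel bends arc around the shared sheet edge
    with a right-handed bend convention; jump-0 hairpins stay in the sheet
    plane and carry no face.
    """
    cons = connections_of(t)
    pos = t.positions
    top_y = (strand_length - 1) * RESIDUE_RISE

    traces = {
        s: _strand_trace(pos[s], t.orient[pos[s] - 1], strand_length)
        for s in range(1, t.n + 1)
    }

    coords: list[np.ndarray] = [traces[1]]
    ranges: list[tuple[int, int]] = [(1, strand_length)]
    faces: list[str | None] = []
    edges: list[str | None] = []
    cursor = strand_length

    for c in cons:
        i = c.index
        exit_pt = traces[i][-1]
        entry_pt = traces[i + 1][0]
        if c.kind == ANTI and c.jump == 0:
            edge_y = top_y + EDGE_CLEARANCE if exit_pt[1] > top_y / 2 else -EDGE_CLEARANCE
            way = [
                np.array([exit_pt[0], edge_y, 0.0]),
                np.array([entry_pt[0], edge_y, 0.0]),
            ]
            conn = _connector(exit_pt, entry_pt, way)
            faces.append(None)
            edges.append(TOP_EDGE if edge_y > 0 else BOTTOM_EDGE)
        elif c.kind == PARA:
            best = None
            for sign in (+1, -1):
                z = sign * CROSSOVER_LIFT
                way = [
                    np.array([exit_pt[0], exit_pt[1], z / 2]),
                    np.array([(exit_pt[0] + entry_pt[0]) / 2, (exit_pt[1] + entry_pt[1]) / 2, z]),
                    np.array([entry_pt[0], entry_pt[1], z / 2]),
                ]
                conn_c = _connector(exit_pt, entry_pt, way)
                motif = np.vstack([traces[i], conn_c, traces[i + 1]])
                axis = traces[i + 1].mean(axis=0) - traces[i].mean(axis=0)
                axis[2] = 0.0
                sense = _screw_sense(motif, axis)
                if best is None or sense > best[0]:
                    best = (sense, sign, conn_c)
            _, sign, conn = best
            faces.append(FRONT if sign > 0 else BACK)
            edges.append(None)
        else:  # antiparallel bend, jump >= 1
            at_top = exit_pt[1] > top_y / 2
            edge_y = top_y + EDGE_CLEARANCE if at_top else -EDGE_CLEARANCE
            sign = c.direction * (1 if t.orient[c.p_start - 1] == UP else -1)
            z = sign * BEND_LIFT
            way = [
                np.array([exit_pt[0], edge_y, z]),
                np.array([entry_pt[0], edge_y, z]),
            ]
            conn = _connector(exit_pt, entry_pt, way)
            faces.append(FRONT if sign > 0 else BACK)
            edges.append(TOP_EDGE if at_top else BOTTOM_EDGE)
        coords.append(conn)
        cursor += len(conn)
        coords.append(traces[i + 1])
        ranges.append((cursor + 1, cursor + strand_length))
        cursor += strand_length

    return MockStructure(
        topology=t,
        coords=np.vstack(coords),
        strand_ranges=tuple(ranges),
        connector_faces=tuple(faces),
        connector_edges=tuple(edges),
    )


TOP_EDGE = "top"
BOTTOM_EDGE = "bottom"


def write_mock_pdb(mock: MockStructure, dest: str | Path) -> None:
    """Write the mock as a Cα-only single-chain PDB file."""
    import gemmi

    st = gemmi.Structure()
    st.name = format_topology(mock.topology)
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (x, y, z) in enumerate(mock.coords, start=1):
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(dest))
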