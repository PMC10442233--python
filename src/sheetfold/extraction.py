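"""Deriving a sheet topology from protein coordinates.

The pipeline mirrors how sheet topologies are assigned in curated domain
sets: strands (provided externally, e.g. from a DSSP/STRIDE run, or detected
from backbone hydrogen-bond ladders) become nodes of a pairing graph whose
edges link neighboring strands supported by at least two main-chain
hydrogen bonds; open, unbranched sheets of at least three strands are read
off the graph and converted to canonical :class:`~sheetfold.topology.SheetTopology`
objects.

Qualification criteria for a sheet:

1. constituent strands are longer than two residues;
2. the sheet has at least three strands;
3. neighboring strands share at least two main-chain hydrogen bonds
   (for Cα-only models a distance-based contact criterion stands in);
4. no strand of another qualifying sheet is inserted, along the sequence,
   between consecutive strands of this sheet.

Branched sheets (a strand with more than two neighbors) and barrels
(cyclic pairing) are discarded.  Sheets spanning several chains are not
assembled: pairings are only considered within one chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import gemmi
import networkx as nx
import numpy as np

from .topology import SheetTopology, canonicalize

MIN_STRAND_RESIDUES = 3        # "more than two residues"
MIN_SHEET_STRANDS = 3
MIN_HBONDS = 2                 # hydrogen bonds per neighboring strand pair

#: geometric hydrogen-bond criterion (no explicit hydrogens):
HBOND_NO_DISTANCE = 3.5        # N···O distance cutoff, Å
HBOND_CON_ANGLE = 90.0         # minimum C–O···N angle, degrees

#: Cα-only fallback pairing: neighboring strands share >= MIN_HBONDS residue
#: pairs with Cα–Cα distance below this cutoff (Å)
CA_CONTACT_DISTANCE = 5.5


class ExtractionError(ValueError):
    """Raised for unusable structures or inconsistent pairing."""


@dataclass(frozen=True)
class StrandSegment:
    """A β-strand: chain, inclusive residue range, direction vector."""

    chain: str
    start: int
    end: int
    direction: tuple[float, float, float]

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:  # pragma: no cover
        return f"{self.chain}:{self.start}-{self.end}"


@dataclass
class Model:
    """Per-residue backbone coordinates of the first model of a structure."""

    atoms: dict[tuple[str, int], dict[str, np.ndarray]]   # (chain, resnum) → atom → xyz
    chains: tuple[str, ...]
    ca_only: bool


def parse_structure(path: str | Path) -> Model:
    """Read a PDB file: first model, altloc A preferred, backbone atoms."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ExtractionError(f"{path}: no models in structure")
    st.setup_entities()
    model = st[0]
    atoms: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for chain in model:
        for res in chain:
            entry: dict[str, np.ndarray] = {}
            for atom in res:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                if atom.name in ("N", "CA", "C", "O"):
                    entry[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z]
                    )
            if "CA" in entry:
                atoms[(chain.name, res.seqid.num)] = entry
    if not atoms:
        raise ExtractionError(f"{path}: no protein residues with Cα atoms")
    chains = tuple(dict.fromkeys(c for c, _ in atoms))
    ca_only = all(set(e) == {"CA"} for e in atoms.values())
    if ca_only:
        import warnings

        warnings.warn(
            f"{path}: Cα-only coordinates; hydrogen-bond detection disabled, "
            "using Cα contact pairing",
            stacklevel=2,
        )
    return Model(atoms=atoms, chains=chains, ca_only=ca_only)


# ---------------------------------------------------------------------------
# Strands
# ---------------------------------------------------------------------------

def read_strand_table(source: str | Path | TextIO) -> list[tuple[str, int, int]]:
    """Read the external strand TSV (columns: chain, start, end)."""
    import pandas as pd

    df = pd.read_csv(source, sep="\t", dtype={"chain": str, "start": int, "end": int})
    missing = [c for c in ("chain", "start", "end") if c not in df.columns]
    if missing:
        raise ValueError(f"strand table: missing columns {missing}")
    return [(r.chain, int(r.start), int(r.end)) for r in df.itertuples()]


def _segment(model: Model, chain: str, start: int, end: int) -> StrandSegment | None:
    cas = [
        model.atoms[(chain, i)]["CA"]
        for i in range(start, end + 1)
        if (chain, i) in model.atoms
    ]
    if len(cas) < MIN_STRAND_RESIDUES:
        return None
    d = cas[-1] - cas[0]
    norm = np.linalg.norm(d)
    if norm == 0:
        return None
    return StrandSegment(chain, start, end, tuple(d / norm))


def strands_from_ranges(
    model: Model, ranges: Iterable[tuple[str, int, int]]
) -> list[StrandSegment]:
    """Instantiate strand segments, dropping those of ≤ 2 residues."""
    out = []
    for chain, start, end in ranges:
        seg = _segment(model, chain, start, end)
        if seg is not None:
            out.append(seg)
    return out


def _hbonds(model: Model) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """Main-chain N–H···O=C bonds by the geometric criterion (donor, acceptor)."""
    donors = [(key, e["N"]) for key, e in model.atoms.items() if "N" in e]
    acceptors = [
        (key, e["O"], e["C"]) for key, e in model.atoms.items() if "O" in e and "C" in e
    ]
    bonds = set()
    for dkey, n in donors:
        for akey, o, c in acceptors:
            if dkey == akey:
                continue
            v = n - o
            dist = np.linalg.norm(v)
            if dist > HBOND_NO_DISTANCE:
                continue
            co = o - c
            cos = np.dot(co, v) / (np.linalg.norm(co) * dist)
            angle = np.degrees(np.arccos(np.clip(cos, -1, 1)))
            # angle between the C=O bond direction and O···N must be open
            if angle <= 180.0 - HBOND_CON_ANGLE:
                bonds.add((dkey, akey))
    return bonds


def detect_strands(model: Model) -> list[StrandSegment]:
    """Detect strands from backbone hydrogen-bond ladders.

    A residue is a ladder residue when it donates or accepts a main-chain
    hydrogen bond to a residue at least three positions away in sequence (or
    in another chain); runs of at least three consecutive ladder residues
    form strands.  This is a convenience stand-in for an external secondary
    structure assignment, not a faithful DSSP/STRIDE reimplementation.
    """
    if model.ca_only:
        raise ExtractionError("strand detection needs backbone N/C/O atoms")
    ladder: set[tuple[str, int]] = set()
    for (c1, r1), (c2, r2) in _hbonds(model):
        if c1 != c2 or abs(r1 - r2) >= 3:
            ladder.add((c1, r1))
            ladder.add((c2, r2))
    out = []
    for chain in model.chains:
        nums = sorted(r for c, r in ladder if c == chain)
        run: list[int] = []
        for r in nums + [None]:
            if run and (r is None or r != run[-1] + 1):
                seg = _segment(model, chain, run[0], run[-1])
                if seg is not None:
                    out.append(seg)
                run = []
            if r is not None:
                run.append(r)
    return out


# ---------------------------------------------------------------------------
# Pairing graph
# ---------------------------------------------------------------------------

def build_pairing_graph(
    model: Model, strands: Sequence[StrandSegment] | None = None
) -> nx.Graph:
    """Graph of strand segments; edges = supported neighboring-strand pairs.

    Edges carry ``n_bonds`` (hydrogen bonds, or Cα contacts for Cα-only
    models) and ``relation`` (``"para"``/``"anti"`` from the direction-vector
    dot product).  Pairs in different chains are not linked.
    """
    if strands is None:
        strands = detect_strands(model)
    strands = [s for s in strands if s.length >= MIN_STRAND_RESIDUES]
    g = nx.Graph()
    g.add_nodes_from(strands)
    if not model.ca_only:
        bonds = _hbonds(model)
        pair_bonds: dict[tuple[int, int], int] = {}
        index = {}
        for k, s in enumerate(strands):
            for r in range(s.start, s.end + 1):
                index[(s.chain, r)] = k
        for dkey, akey in bonds:
            a, b = index.get(dkey), index.get(akey)
            if a is None or b is None or a == b:
                continue
            key = (min(a, b), max(a, b))
            pair_bonds[key] = pair_bonds.get(key, 0) + 1
        for (a, b), nb in pair_bonds.items():
            sa, sb = strands[a], strands[b]
            if sa.chain != sb.chain or nb < MIN_HBONDS:
                continue
            rel = "para" if np.dot(sa.direction, sb.direction) > 0 else "anti"
            g.add_edge(sa, sb, n_bonds=nb, relation=rel)
    else:
        for i, sa in enumerate(strands):
            for sb in strands[i + 1 :]:
                if sa.chain != sb.chain:
                    continue
                ca_a = [
                    model.atoms[(sa.chain, r)]["CA"]
                    for r in range(sa.start, sa.end + 1)
                    if (sa.chain, r) in model.atoms
                ]
                ca_b = [
                    model.atoms[(sb.chain, r)]["CA"]
                    for r in range(sb.start, sb.end + 1)
                    if (sb.chain, r) in model.atoms
                ]
                contacts = sum(
                    1
                    for pa in ca_a
                    for pb in ca_b
                    if np.linalg.norm(pa - pb) <= CA_CONTACT_DISTANCE
                )
                if contacts >= MIN_HBONDS:
                    rel = (
                        "para"
                        if np.dot(sa.direction, sb.direction) > 0
                        else "anti"
                    )
                    g.add_edge(sa, sb, n_bonds=contacts, relation=rel)
    return g


def assemble_sheets(graph: nx.Graph) -> list[list[StrandSegment]]:
    """Open, unbranched sheets of ≥ 3 strands, as ordered strand paths.

    Components containing a branch (degree ≥ 3) or a cycle are discarded;
    afterwards, a sheet is discarded when another retained sheet inserts a
    strand, along the sequence, between two of its sequence-consecutive
    strands.
    """
    candidates: list[list[StrandSegment]] = []
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if len(comp) < MIN_SHEET_STRANDS:
            continue
        if any(d >= 3 for _, d in sub.degree):
            continue
        if len(sub.edges) != len(comp) - 1:   # cycle (barrel)
            continue
        ends = [n for n, d in sub.degree if d == 1]
        path = [ends[0]]
        while len(path) < len(comp):
            nxt = [n for n in sub.neighbors(path[-1]) if n not in path]
            path.append(nxt[0])
        candidates.append(path)

    def inserts_into(other: list[StrandSegment], sheet: list[StrandSegment]) -> bool:
        ordered = sorted(sheet, key=lambda s: s.start)
        for s1, s2 in zip(ordered[:-1], ordered[1:]):
            for o in other:
                if o.chain == s1.chain and s1.end < o.start and o.end < s2.start:
                    return True
        return False

    kept = []
    for sheet in candidates:
        if any(
            other is not sheet and inserts_into(other, sheet)
            for other in candidates
        ):
            continue
        kept.append(sheet)
    return kept


def sheet_to_topology(sheet: Sequence[StrandSegment], graph: nx.Graph) -> SheetTopology:
    """Canonical topology of one sheet path.

    Strands are numbered by sequence order, positions by path order (the
    path direction is arbitrary — canonicalization absorbs it), and
    orientations are propagated along the path from the pairwise para/anti
    edge labels.
    """
    chains = {s.chain for s in sheet}
    if len(chains) > 1:
        raise ExtractionError(f"sheet spans multiple chains: {sorted(chains)}")
    by_seq = sorted(sheet, key=lambda s: s.start)
    number = {s: i for i, s in enumerate(by_seq, start=1)}
    order = tuple(number[s] for s in sheet)
    orient = ["u"]
    for a, b in zip(sheet[:-1], sheet[1:]):
        rel = graph.edges[a, b]["relation"]
        prev = orient[-1]
        orient.append(prev if rel == "para" else ("d" if prev == "u" else "u"))
    return canonicalize(SheetTopology(order, tuple(orient)))


def extract_topologies(
    path: str | Path, strands: Iterable[tuple[str, int, int]] | None = None
) -> list[SheetTopology]:
    """End-to-end convenience: PDB (+ optional strand ranges) → topologies."""
    model = parse_structure(path)
    segs = strands_from_ranges(model, strands) if strands is not None else None
    graph = build_pairing_graph(model, segs)
    return [sheet_to_topology(sheet, graph) for sheet in assemble_sheets(graph)]
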