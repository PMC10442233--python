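"""Frustration classification of β-sheet topologies.

The chain segment linking two sequence-consecutive strands of a sheet (a
β-X-β motif, where X may be a loop or contain helices) is modelled as a
*connection* with a small set of geometric attributes, and three empirical
rules are evaluated over the connections of a topology:

jump-distance rule
    Connections skipping many sheet positions are disfavored: a parallel
    connection must have jump distance < 4 and an antiparallel one < 2,
    where the jump distance is the number of strands lying spatially between
    the two strands.  Exception: the antiparallel jump-2 connection of the
    Greek-key arrangement and its circular permutations.

connection-overlap rule
    Two connections competing for the same region of the same sheet face
    (S-type geometry) are disfavored over connections on different faces
    (D-type).

connection-ending rule
    When two parallel-type connections end on strands that sit next to each
    other and point the same way, they should arrive from the same face
    (S-type); arriving from different faces (D-type) is disfavored.

A topology violating none of the rules is *frustration-free* and predicted
to be a realizable fold; otherwise it is *frustrated*.

Geometry model
--------------
Connections are laid out on a flat "board": x is the sheet position axis,
y ∈ [0, 1] runs from the bottom to the top strand ends, and each connection
is assigned a face (front/back) of the board.

* A parallel connection leaves the C-end of its first strand, crosses one
  face of the sheet (right-handed crossover, per Richardson's rule) and
  enters the N-end of the second strand: a diagonal from edge to edge.  Its
  face is ``front`` iff ``travel_direction * orientation > 0`` (the global
  front/back sign is a convention; only relative faces matter).
* An antiparallel connection with jump ≥ 1 bends around the sheet edge
  (top or bottom, fixed by the strand orientations), arcing over the ends
  of the intervening strands.
* An antiparallel jump-0 connection is a hairpin at the sheet edge between
  adjacent strands; it crosses no face and never collides with anything.

Overlap (S-type) collisions are read off this board:

* two parallel crossovers on the same face collide when their position
  spans overlap with positive length — except when the spans have equal
  length and the same travel direction, in which case the crossovers run
  parallel, can stack side by side, and do not collide (this is exactly the
  geometry of the knot-forming all-parallel 3142 fold);
* an edge bend collides with any crossover that terminates at the bend's
  edge strictly inside the bend's span (the bend occupies the whole edge
  strip above those strand ends, on both sides of the sheet plane);
* two bends around the same edge collide when their spans overlap with
  positive length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, TextIO

from .topology import (
    DOWN,
    UP,
    SheetTopology,
    canonicalize,
    format_topology,
    iter_canonical,
)

PARA = "para"
ANTI = "anti"
FRONT = "front"
BACK = "back"
TOP = "top"
BOTTOM = "bottom"

JUMP_RULE = "jump_distance"
OVERLAP_RULE = "overlap"
ENDING_RULE = "ending"

#: maximum allowed jump distances (rule thresholds)
MAX_PARA_JUMP = 3
MAX_ANTI_JUMP = 1


class Violation(NamedTuple):
    rule: str
    connections: tuple[int, ...]


@dataclass(frozen=True)
class Connection:
    """The chain link (β-X-β motif) from strand ``index`` to ``index + 1``."""

    index: int
    p_start: int
    p_end: int
    kind: str
    jump: int
    span: tuple[int, int]
    face: str | None
    ending_side: str | None

    @property
    def direction(self) -> int:
        """+1 for rightward travel across the sheet, -1 for leftward."""
        return 1 if self.p_end > self.p_start else -1


@dataclass(frozen=True)
class Classification:
    topology: SheetTopology
    violations: tuple[Violation, ...]

    @property
    def frustration_free(self) -> bool:
        return not self.violations


# ---------------------------------------------------------------------------
# Greek-key exemption
# ---------------------------------------------------------------------------

def _images(order: tuple[int, ...], orient: tuple[str, ...]):
    ro = tuple(reversed(order))
    fl = tuple(UP if c == DOWN else DOWN for c in orient)
    return (
        (order, orient),
        (order, fl),
        (ro, tuple(reversed(orient))),
        (ro, tuple(reversed(fl))),
    )


def _canon_tuple(order, orient):
    return min(
        _images(order, orient),
        key=lambda im: (im[0], tuple(0 if c == UP else 1 for c in im[1])),
    )


def _greek_key_patterns() -> frozenset:
    """Canonical forms of the Greek key and its chain circular permutations.

    The base arrangement places strands 4-1-2-3 across the sheet with
    alternating orientations: two hairpins (s1-s2, s2-s3) and one
    antiparallel jump-2 connection (s3-s4) closing onto s1.  Restarting the
    chain at each strand yields the circular permutants (one of which is the
    plain meander and carries no jump-2 connection).
    """
    base_order, base_orient = (4, 1, 2, 3), (DOWN, UP, DOWN, UP)
    pats = set()
    for shift in range(4):
        relabeled = tuple(((s - 1 - shift) % 4) + 1 for s in base_order)
        pats.add(_canon_tuple(relabeled, base_orient))
    return frozenset(pats)


GREEK_KEY_PATTERNS = _greek_key_patterns()


# ---------------------------------------------------------------------------
# Tuple-level core (fast path)
# ---------------------------------------------------------------------------

def _raw_connections(order, orient):
    """List of (i, ps, pe, o_start, o_end, is_para, jump, direction)."""
    n = len(order)
    pos = [0] * (n + 1)
    for p, s in enumerate(order, 1):
        pos[s] = p
    cons = []
    for i in range(1, n):
        ps, pe = pos[i], pos[i + 1]
        os_, oe = orient[ps - 1], orient[pe - 1]
        cons.append(
            (i, ps, pe, os_, oe, os_ == oe, abs(pe - ps) - 1, 1 if pe > ps else -1)
        )
    return cons


def _gk_exempt_tuple(c, order, orient) -> bool:
    _, ps, pe, _, _, para, jump, _ = c
    if para or jump != 2:
        return False
    lo, hi = (ps, pe) if ps < pe else (pe, ps)
    strands = order[lo - 1 : hi]
    ranks = {s: k + 1 for k, s in enumerate(sorted(strands))}
    window = tuple(ranks[s] for s in strands)
    return _canon_tuple(window, orient[lo - 1 : hi]) in GREEK_KEY_PATTERNS


def _violations_tuple(order, orient) -> list[Violation]:
    cons = _raw_connections(order, orient)
    viol: list[Violation] = []

    # --- jump-distance rule -------------------------------------------------
    for c in cons:
        i, _, _, _, _, para, jump, _ = c
        if para:
            if jump > MAX_PARA_JUMP:
                viol.append(Violation(JUMP_RULE, (i,)))
        elif jump > MAX_ANTI_JUMP and not _gk_exempt_tuple(c, order, orient):
            viol.append(Violation(JUMP_RULE, (i,)))

    # --- connection-overlap rule -------------------------------------------
    m = len(cons)
    for a in range(m):
        ia, psa, pea, osa, oea, para_a, ja, da = cons[a]
        bend_a = (not para_a) and ja >= 1
        hp_a = (not para_a) and ja == 0
        if hp_a:
            continue
        loa, hia = (psa, pea) if psa < pea else (pea, psa)
        for b in range(a + 1, m):
            ib, psb, peb, osb, oeb, para_b, jb, db = cons[b]
            bend_b = (not para_b) and jb >= 1
            hp_b = (not para_b) and jb == 0
            if hp_b:
                continue
            lob, hib = (psb, peb) if psb < peb else (peb, psb)
            hit = False
            if para_a and para_b:
                # same face: front iff direction * orientation_sign > 0
                fa = da if osa == UP else -da
                fb = db if osb == UP else -db
                if fa == fb and min(hia, hib) - max(loa, lob) > 0:
                    hit = not ((hia - loa) == (hib - lob) and da == db)
            elif bend_a and bend_b:
                ea = osa  # exit edge: top iff start strand points up
                eb = osb
                if ea == eb and min(hia, hib) - max(loa, lob) > 0:
                    hit = True
            else:
                if bend_a:
                    edge, blo, bhi = osa, loa, hia
                    d_ps, d_pe, d_os, d_oe = psb, peb, osb, oeb
                else:
                    edge, blo, bhi = osb, lob, hib
                    d_ps, d_pe, d_os, d_oe = psa, pea, osa, oea
                # crossover terminates at the bend's edge strictly inside span:
                # exit end is at the top iff the start strand points up; the
                # entry (N) end is at the top iff the end strand points down.
                if (d_os == edge and blo < d_ps < bhi) or (
                    (d_oe != edge) and blo < d_pe < bhi
                ):
                    hit = True
            if hit:
                viol.append(Violation(OVERLAP_RULE, (ia, ib)))

    # --- connection-ending rule ----------------------------------------------
    for a in range(m):
        ia, psa, pea, osa, oea, para_a, ja, da = cons[a]
        if not para_a:
            continue
        for b in range(a + 1, m):
            ib, psb, peb, osb, oeb, para_b, jb, db = cons[b]
            if not para_b or ib - ia == 1:
                continue  # chain-consecutive motifs are geometrically coupled
            if abs(pea - peb) != 1 or oea != oeb:
                continue
            ha = da if oea == UP else -da
            hb = db if oeb == UP else -db
            if ha != hb:
                viol.append(Violation(ENDING_RULE, (ia, ib)))
    return viol


def _frustrated(order, orient) -> bool:
    """Fast boolean used by :func:`classification_counts`."""
    return bool(_violations_tuple(order, orient))


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def connection_face(kind: str, jump: int, direction: int, orient_start: str) -> str | None:
    """Face crossed by a connection (``None`` for jump-0 hairpins).

    For a parallel crossover this realizes the right-handed preference: with
    the strand pointing up, rightward travel crosses the front face and
    leftward travel the back face.  Antiparallel bends are labelled with the
    same convention (right-handed bend); note that the overlap rule treats a
    bend as occupying its whole edge strip, so its face label never changes a
    verdict.
    """
    if kind == ANTI and jump == 0:
        return None
    sign = direction * (1 if orient_start == UP else -1)
    return FRONT if sign > 0 else BACK


def ending_side(kind: str, direction: int, orient_end: str) -> str | None:
    """Face from which a connection arrives at its second strand.

    Defined for parallel connections (it equals the crossover face, read at
    the entry end); antiparallel connections return ``None``.
    """
    if kind != PARA:
        return None
    sign = direction * (1 if orient_end == UP else -1)
    return FRONT if sign > 0 else BACK


def connections_of(t: SheetTopology) -> list[Connection]:
    """The ``n - 1`` connections of a topology, with faces populated."""
    out = []
    for i, ps, pe, os_, oe, para, jump, d in _raw_connections(t.order, t.orient):
        kind = PARA if para else ANTI
        out.append(
            Connection(
                index=i,
                p_start=ps,
                p_end=pe,
                kind=kind,
                jump=jump,
                span=(min(ps, pe), max(ps, pe)),
                face=connection_face(kind, jump, d, os_),
                ending_side=ending_side(kind, d, oe),
            )
        )
    return out


def greek_key_exempt(c: Connection, t: SheetTopology) -> bool:
    """True iff ``c`` is the exempt antiparallel jump-2 connection of a
    Greek-key window (or one of its circular permutants).

    The window is the four consecutive sheet positions spanned by the
    connection; its strands are relabelled by sequence rank and compared,
    up to sheet rotation, against the Greek-key patterns.
    """
    raw = _raw_connections(t.order, t.orient)[c.index - 1]
    return _gk_exempt_tuple(raw, t.order, t.orient)


def _select(violations: Iterable[Violation], rule: str) -> list[Violation]:
    return [v for v in violations if v.rule == rule]


def check_jump_rule(t: SheetTopology) -> list[Violation]:
    return _select(_violations_tuple(t.order, t.orient), JUMP_RULE)


def check_overlap_rule(t: SheetTopology) -> list[Violation]:
    return _select(_violations_tuple(t.order, t.orient), OVERLAP_RULE)


def check_ending_rule(t: SheetTopology) -> list[Violation]:
    return _select(_violations_tuple(t.order, t.orient), ENDING_RULE)


def classify_topology(t: SheetTopology) -> Classification:
    """Evaluate all three rules; frustration-free iff no violations."""
    return Classification(t, tuple(_violations_tuple(t.order, t.orient)))


def classify_all(n: int) -> Iterator[Classification]:
    """One :class:`Classification` per canonical topology, in canonical order."""
    for order, orient in iter_canonical(n):
        yield Classification(
            SheetTopology(order, orient), tuple(_violations_tuple(order, orient))
        )


def classification_counts(n: int) -> tuple[int, int]:
    """(frustration-free, frustrated) counts over all canonical topologies."""
    free = frustrated = 0
    for order, orient in iter_canonical(n):
        if _violations_tuple(order, orient):
            frustrated += 1
        else:
            free += 1
    return free, frustrated


def format_violations(violations: Iterable[Violation]) -> str:
    """Semicolon-joined ``rule(i[,j])`` report column."""
    return ";".join(
        f"{v.rule}({','.join(str(i) for i in v.connections)})" for v in violations
    )


def write_classification_tsv(classifications: Iterable[Classification], fh: TextIO) -> int:
    fh.write("topology\tn\tfrustration_free\tviolations\n")
    k = 0
    for c in classifications:
        fh.write(
            f"{format_topology(c.topology)}\t{c.topology.n}\t"
            f"{str(c.frustration_free).lower()}\t{format_violations(c.violations)}\n"
        )
        k += 1
    return k


def frustration_free_topologies(n: int) -> list[SheetTopology]:
    """Canonical frustration-free topologies for an ``n``-stranded sheet."""
    return [c.topology for c in classify_all(n) if c.frustration_free]
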