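"""Open β-sheet topologies: representation, parsing, symmetry and enumeration.

A β-sheet topology abstracts an αβ-fold down to the arrangement of its
β-strands in one open (non-barrel) sheet: which strand, numbered along the
chain, sits at each sheet position (left to right), and whether it points up
or down.  A sheet of ``n`` strands is therefore a pair of a permutation of
``1..n`` and a length-``n`` orientation vector.

Two raw grids describe the same physical fold when they are related by one of
the three 180° rigid rotations of the sheet (about the sheet normal, the
in-plane strand axis, or the in-plane position axis).  Mirror reflections are
*not* identified: connection handedness makes folds chiral, so enantiomeric
sheets are distinct objects.  Each symmetry orbit has exactly four members
(a permutation of distinct labels can never equal its own reversal), giving
``n!·2^(n-2)`` distinct topologies for an ``n``-stranded sheet.

Orientation vectors are indexed by sheet *position* (left→right).  Use
:func:`orient_by_position` to convert per-strand orientation input.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product
from typing import Iterable, Iterator, TextIO

UP = "u"
DOWN = "d"

#: arrow glyphs accepted on input and normalized to u/d
_ARROWS = {"↑": UP, "↓": DOWN, "^": UP, "v": DOWN, "u": UP, "d": DOWN}

_MIN_STRANDS = 3
_MAX_STRANDS = 9


class TopologyError(ValueError):
    """Raised for malformed or inconsistent topology input."""


@dataclass(frozen=True, order=False)
class SheetTopology:
    """An open β-sheet topology.

    Parameters
    ----------
    order:
        ``order[p]`` (0-based ``p``) is the sequence index (1-based) of the
        strand occupying sheet position ``p+1``, positions running left to
        right.
    orient:
        ``orient[p]`` is ``"u"`` or ``"d"``, the direction of the strand at
        position ``p+1``.
    """

    order: tuple[int, ...]
    orient: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.order)
        if n < 2:
            raise TopologyError(f"order: need at least 2 strands, got {n}")
        if n > _MAX_STRANDS:
            raise TopologyError(
                f"order: at most {_MAX_STRANDS} strands supported, got {n}"
            )
        if sorted(self.order) != list(range(1, n + 1)):
            raise TopologyError(
                f"order: {self.order!r} is not a permutation of 1..{n}"
            )
        if len(self.orient) != n:
            raise TopologyError(
                f"orient: length {len(self.orient)} does not match {n} strands"
            )
        bad = set(self.orient) - {UP, DOWN}
        if bad:
            raise TopologyError(f"orient: characters {sorted(bad)!r} not in {{u,d}}")

    @property
    def n(self) -> int:
        """Number of strands."""
        return len(self.order)

    @property
    def positions(self) -> dict[int, int]:
        """Map strand index (1-based) → sheet position (1-based)."""
        return {s: p for p, s in enumerate(self.order, start=1)}

    def orientation_of_strand(self, strand: int) -> str:
        """Orientation (u/d) of a strand given by its sequence index."""
        return self.orient[self.positions[strand] - 1]

    def sort_key(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """Total order: order vector first, then orientations with u < d."""
        return self.order, tuple(0 if c == UP else 1 for c in self.orient)

    def __str__(self) -> str:  # pragma: no cover - trivial
        return format_topology(self)


def parse_topology(text: str) -> SheetTopology:
    """Parse a topology string ``"<digits>:<u/d letters>"``.

    Arrow glyphs (``↑``/``↓``) are accepted in the orientation field and
    normalized.  Example: ``"1342:uddd"``.
    """
    parts = text.strip().split(":")
    if len(parts) != 2:
        raise TopologyError(f"topology string {text!r}: expected one ':' separator")
    digits, arrows = parts
    if not digits.isdigit() or not digits:
        raise TopologyError(f"order: {digits!r} is not a digit string")
    order = tuple(int(c) for c in digits)
    try:
        orient = tuple(_ARROWS[c] for c in arrows)
    except KeyError as exc:
        raise TopologyError(f"orient: unrecognized character {exc.args[0]!r}") from None
    t = SheetTopology(order, orient)
    if t.n < _MIN_STRANDS:
        raise TopologyError(f"order: need at least {_MIN_STRANDS} strands, got {t.n}")
    return t


def format_topology(t: SheetTopology) -> str:
    """Inverse of :func:`parse_topology` (ASCII u/d dialect)."""
    return "".join(str(s) for s in t.order) + ":" + "".join(t.orient)


def orient_by_position(order: Iterable[int], strand_orient: Iterable[str]) -> tuple[str, ...]:
    """Convert per-*strand* orientations to the per-*position* convention.

    ``strand_orient[i]`` is the orientation of strand ``i+1`` (sequence
    numbering); the result is indexed by sheet position.
    """
    order = tuple(order)
    strand_orient = tuple(strand_orient)
    return tuple(strand_orient[s - 1] for s in order)


def _flip(orient: tuple[str, ...]) -> tuple[str, ...]:
    return tuple(UP if c == DOWN else DOWN for c in orient)


def symmetry_images(t: SheetTopology) -> set[SheetTopology]:
    """The four images of ``t`` under the proper rotation group of the sheet.

    The three non-identity images are the 180° rotations about the sheet
    normal (positions reversed, orientations flipped), about the in-plane
    strand axis (positions reversed, orientations kept) and about the
    in-plane position axis (positions kept, orientations flipped).  The set
    always has cardinality 4: no permutation of distinct labels equals its
    own reversal.
    """
    ro = tuple(reversed(t.order))
    return {
        t,
        SheetTopology(t.order, _flip(t.orient)),
        SheetTopology(ro, tuple(reversed(t.orient))),
        SheetTopology(ro, tuple(reversed(_flip(t.orient)))),
    }


def canonicalize(t: SheetTopology) -> SheetTopology:
    """Lexicographically smallest symmetry image (u < d); orbit-constant."""
    return min(symmetry_images(t), key=SheetTopology.sort_key)


def enumerate_topologies(n: int) -> list[SheetTopology]:
    """All canonical ``n``-strand topologies, sorted by the canonical order.

    The count is ``n!·2^(n-2)``.  Enumeration is direct: keep the smaller
    member of each (permutation, reversal) pair and orientation vectors whose
    first entry is ``u``; these are exactly the canonical representatives.
    """
    if n < 2:
        raise TopologyError(f"n: need at least 2 strands, got {n}")
    if n > 8:
        import warnings

        warnings.warn(
            f"enumerating {n}-strand topologies: {_count(n)} patterns",
            stacklevel=2,
        )
    out: list[SheetTopology] = []
    for order in permutations(range(1, n + 1)):
        if order > tuple(reversed(order)):
            continue
        for tail in product((UP, DOWN), repeat=n - 1):
            out.append(SheetTopology(order, (UP,) + tail))
    out.sort(key=SheetTopology.sort_key)
    return out


def iter_canonical(n: int) -> Iterator[tuple[tuple[int, ...], tuple[str, ...]]]:
    """Memory-light iterator over canonical ``(order, orient)`` tuples.

    Same contents as :func:`enumerate_topologies` but yields bare tuples in
    sorted order without constructing :class:`SheetTopology` objects; used by
    the classification fast path at large ``n``.
    """
    if n < 2:
        raise TopologyError(f"n: need at least 2 strands, got {n}")
    for order in sorted(
        o for o in permutations(range(1, n + 1)) if o < tuple(reversed(o))
    ):
        for tail in product((UP, DOWN), repeat=n - 1):
            yield order, (UP,) + tail


def _count(n: int) -> int:
    import math

    return math.factorial(n) * 2 ** (n - 2)


def expected_count(n: int) -> int:
    """The closed-form topology count ``n!·2^(n-2)``."""
    return _count(n)


def write_topologies_tsv(topologies: Iterable[SheetTopology], fh: TextIO) -> int:
    """Write an enumeration table (columns: topology, n, order, orient)."""
    fh.write("topology\tn\torder\torient\n")
    k = 0
    for t in topologies:
        fh.write(
            f"{format_topology(t)}\t{t.n}\t"
            f"{''.join(map(str, t.order))}\t{''.join(t.orient)}\n"
        )
        k += 1
    return k
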