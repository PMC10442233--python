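import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


from sheetfold.topology import SheetTopology, parse_topology


@pytest.fixture
def meander() -> SheetTopology:
    return parse_topology("1234:udud")


@pytest.fixture
def knot() -> SheetTopology:
    """All-parallel 3142 strand order (knot-forming fold)."""
    return parse_topology("3142:uuuu")


@pytest.fixture
def greek_key() -> SheetTopology:
    return parse_topology("4123:dudu")


def _backbone_residue(x: float, y: float, n_dx: float, o_dx: float):
    """Backbone atom positions for one idealized ladder residue."""
    return {
        "N": np.array([x + n_dx, y - 0.9, 0.0]),
        "CA": np.array([x, y, 0.0]),
        "C": np.array([x + 0.6 * np.sign(o_dx or 1), y + 0.5, 0.0]),
        "O": np.array([x + o_dx, y, 0.0]),
    }


def write_ladder_pdb(path, n_pairs: int = 4, bonds: int | None = None):
    """Two antiparallel strands with a controllable number of N···O contacts.

    Strand A (residues 1..n) runs along +y at x=0 with carbonyl O pointing at
    strand B; strand B (residues 11..10+n) at x=3.6 donates its amide N
    toward A.  Each aligned residue pair yields one hydrogen bond satisfying
    the geometric criterion; ``bonds`` limits how many O atoms point inward.
    """
    if bonds is None:
        bonds = n_pairs
    lines = []
    serial = 0

    def emit(resnum, chain, atoms):
        nonlocal serial
        for name, xyz in atoms.items():
            serial += 1
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} GLY {chain}{resnum:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00 20.00          "
                f"{name[0]:>2s}\n"
            )

    for i in range(n_pairs):
        o_dx = 1.2 if i < bonds else -1.2   # inward O makes the bond
        emit(i + 1, "A", _backbone_residue(0.0, 3.4 * i, n_dx=-1.2, o_dx=o_dx))
    for i in range(n_pairs):
        # antiparallel partner: runs -y, N pointing toward strand A
        emit(11 + i, "A", _backbone_residue(3.6, 3.4 * (n_pairs - 1 - i), n_dx=-1.2, o_dx=1.2))
    path.write_text("".join(lines) + "END\n")
    return path
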