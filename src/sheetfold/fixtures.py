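"""Deterministic synthetic domain tables emulating an ECOD-like hierarchy.

The generator realizes requested occupation ratios exactly: a family with
match fraction ``p`` (a rational) is populated with ``denominator(p)``
domains of which ``numerator(p)`` carry the topology; the remaining domains
carry no qualifying sheet (empty topology field).  Identifiers are derived
deterministically from a seed so tables are byte-reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .topology import parse_topology  # validation on ingest


@dataclass(frozen=True)
class FixtureEntry:
    """One topology's presence specification.

    ``fractions[h][f]`` is the match fraction of family ``f`` in homology
    group ``h``; the topology's resulting observation frequency is
    ``Σ_h mean_f fractions[h][f]``.
    """

    topology: str
    fractions: tuple[tuple[Fraction, ...], ...]

    @staticmethod
    def uniform(
        topology: str,
        homologies: int,
        families_per_homology: int,
        fraction: Fraction | float | str = 1,
    ) -> "FixtureEntry":
        f = Fraction(fraction)
        return FixtureEntry(
            topology,
            tuple(
                tuple(f for _ in range(families_per_homology))
                for _ in range(homologies)
            ),
        )


def make_domain_table_fixture(
    entries: Sequence[FixtureEntry], seed: int = 0
) -> pd.DataFrame:
    """Build a domain table realizing each entry's fractions exactly."""
    rng = random.Random(seed)
    rows = []
    hom_counter = fam_counter = dom_counter = 0
    for entry in entries:
        parse_topology(entry.topology)  # reject malformed fixture specs early
        for fams in entry.fractions:
            hom_counter += 1
            hom = f"H{hom_counter:04d}"
            for frac in fams:
                frac = Fraction(frac)
                if not 0 <= frac <= 1:
                    raise ValueError(f"fixture fraction {frac} outside [0, 1]")
                fam_counter += 1
                fam = f"F{fam_counter:04d}"
                n_dom = max(frac.denominator, 1)
                n_match = frac.numerator * (n_dom // frac.denominator)
                flags = [True] * n_match + [False] * (n_dom - n_match)
                rng.shuffle(flags)
                for has in flags:
                    dom_counter += 1
                    rows.append(
                        {
                            "domain_id": f"D{dom_counter:06d}",
                            "homology_id": hom,
                            "family_id": fam,
                            "topology": entry.topology if has else "",
                        }
                    )
    return pd.DataFrame(rows, columns=["domain_id", "homology_id", "family_id", "topology"])


def write_domain_table(df: pd.DataFrame, dest: str | Path | TextIO) -> None:
    df.to_csv(dest, sep="\t", index=False)


def observed_split_fixture(
    topologies: Iterable[str], n_observed: int, seed: int = 0
) -> pd.DataFrame:
    """Mark the first ``n_observed`` of ``topologies`` with frequency 1 each.

    Used to mirror, at the construction level, a split of frustration-free
    topologies into observed and unobserved ones.
    """
    selected = list(topologies)[:n_observed]
    entries = [FixtureEntry.uniform(t, homologies=1, families_per_homology=1) for t in selected]
    return make_domain_table_fixture(entries, seed=seed)
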