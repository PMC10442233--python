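"""Observation frequencies of sheet topologies over a domain hierarchy.

Domains are grouped in two evolutionary levels, Family (sequence-level
groups) nested inside Homology (superfamily-level groups), mirroring the
ECOD hierarchy.  For one Homology group ``i`` the occupation ratio of a
topology is

    OR(i) = ( Σ_j R_Family(j) ) / N_Family,

where ``R_Family(j)`` is the fraction of the ``j``-th Family's domains whose
(canonical) sheet topology equals the query, and ``N_Family`` the number of
Families in the group.  The observation frequency of a topology is the sum
of OR(i) over all Homology groups; a topology is labelled *unobserved* when
its frequency is strictly below the threshold (default 1/4 — evolutionarily
unstable topologies that survive in almost no family count as unobserved).

The exchange format is a TSV with columns ``domain_id``, ``homology_id``,
``family_id`` and ``topology`` (a topology string, or empty when the domain
has no qualifying sheet).  A domain may appear on several rows with distinct
topologies (one per qualifying sheet); exact ``(domain_id, topology)``
duplicates are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, TextIO

import pandas as pd

from .rules import classify_all
from .topology import SheetTopology, TopologyError, canonicalize, format_topology, parse_topology

REQUIRED_COLUMNS = ("domain_id", "homology_id", "family_id", "topology")

#: frequency threshold below which a topology counts as unobserved
DEFAULT_THRESHOLD = Fraction(1, 4)

OBSERVED = "observed"
UNOBSERVED = "unobserved"


@dataclass(frozen=True)
class FrequencyResult:
    topology: str
    frequency: float
    status: str

    @property
    def observed(self) -> bool:
        return self.status == OBSERVED


class ObservationTable:
    """Validated, canonicalized domain records."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def homology_groups(self) -> list[str]:
        return sorted(self.frame["homology_id"].unique())


def _canonical_string(text: str) -> str:
    return format_topology(canonicalize(parse_topology(text)))


def read_domain_table(source: str | Path | TextIO) -> ObservationTable:
    """Read and validate the domain TSV; topologies are canonicalized on ingest."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"domain table: missing columns {missing}")
    canon = []
    for row_no, text in enumerate(df["topology"], start=2):  # 1-based + header
        if text == "":
            canon.append("")
            continue
        try:
            canon.append(_canonical_string(text))
        except TopologyError as exc:
            raise ValueError(f"domain table row {row_no}: {exc}") from exc
    df = df.assign(topology=canon)
    dup = df.duplicated(subset=["domain_id", "topology"])
    if dup.any():
        row_no = int(dup.idxmax()) + 2
        raise ValueError(
            f"domain table row {row_no}: duplicate (domain_id, topology) record"
        )
    fam2hom = df.groupby("family_id")["homology_id"].nunique()
    bad = fam2hom[fam2hom > 1]
    if not bad.empty:
        raise ValueError(
            f"domain table: family groups {list(bad.index)} span multiple homology groups"
        )
    return ObservationTable(df)


def occupation_ratio(group: pd.DataFrame, topology: SheetTopology | str) -> float:
    """OR of a topology within one Homology group (mean family fraction)."""
    if len(group) == 0:
        raise ValueError("occupation_ratio: empty homology group")
    query = (
        _canonical_string(topology)
        if isinstance(topology, str)
        else format_topology(canonicalize(topology))
    )
    ratios = []
    for _, fam in group.groupby("family_id"):
        domains = fam["domain_id"].unique()
        having = fam.loc[fam["topology"] == query, "domain_id"].nunique()
        ratios.append(having / len(domains))
    return float(sum(ratios) / len(ratios))


def observation_frequency(table: ObservationTable, topology: SheetTopology | str) -> float:
    """Sum of occupation ratios across Homology groups."""
    if len(table.frame) == 0:
        return 0.0
    return float(
        sum(
            occupation_ratio(group, topology)
            for _, group in table.frame.groupby("homology_id")
        )
    )


def label_observed(
    frequency: float, threshold: Fraction | float = DEFAULT_THRESHOLD
) -> str:
    """``unobserved`` iff frequency < threshold (strict comparison)."""
    threshold = Fraction(threshold)
    if threshold < 0:
        raise ValueError(f"threshold: must be non-negative, got {threshold}")
    return UNOBSERVED if Fraction(frequency).limit_denominator(10**9) < threshold else OBSERVED


def frequency_table(
    n: int,
    table: ObservationTable | None,
    threshold: Fraction | float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Per-topology frequency/status/frustration table for all n-strand topologies."""
    freqs: dict[str, float] = {}
    if table is not None and len(table.frame):
        for _, group in table.frame.groupby("homology_id"):
            n_family = group["family_id"].nunique()
            for (fam_id, topo), sub in group.groupby(["family_id", "topology"]):
                if topo == "" or len(topo.split(":")[0]) != n:
                    continue
                n_dom = group.loc[group["family_id"] == fam_id, "domain_id"].nunique()
                r = sub["domain_id"].nunique() / n_dom
                freqs[topo] = freqs.get(topo, 0.0) + r / n_family
    rows = []
    for c in classify_all(n):
        key = format_topology(c.topology)
        f = freqs.get(key, 0.0)
        rows.append(
            {
                "topology": key,
                "frequency": f,
                "status": label_observed(f, threshold),
                "frustration_free": c.frustration_free,
            }
        )
    return pd.DataFrame(rows)


def predict_novel_folds(
    n: int,
    table: ObservationTable | None = None,
    threshold: Fraction | float = DEFAULT_THRESHOLD,
) -> list[FrequencyResult]:
    """Frustration-free topologies whose frequency falls below the threshold.

    With no (or an empty) table every frustration-free topology is returned:
    nothing has been observed.  Results are sorted by frequency, then by the
    canonical topology order.
    """
    df = frequency_table(n, table, threshold)
    novel = df[(df["frustration_free"]) & (df["status"] == UNOBSERVED)]
    return [
        FrequencyResult(r.topology, float(r.frequency), UNOBSERVED)
        for r in novel.sort_values(
            ["frequency", "topology"], kind="stable"
        ).itertuples()
    ]


def write_frequency_tsv(df: pd.DataFrame, fh: TextIO) -> int:
    df.to_csv(fh, sep="\t", index=False)
    return len(df)
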