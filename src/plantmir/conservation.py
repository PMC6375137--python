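"""Conservation analysis of sRNA reads against registered plant mature miRNAs.

Two questions are answered here. First, which sequenced sRNAs are *conserved
miRNA candidates*, i.e. exactly identical to a registered plant mature miRNA
(the conservative, reproducible reading of a registry scan). Second, how
close is a *predicted* mature sequence to the registry: identical, similar
but not identical (global edit distance 1..max_dist, default 3), or novel.

Reference sets follow the miRBase mature-FASTA dialect: identifiers carry a
3-letter species prefix ("ath-miR168a-5p"), from which a family label
("miR168") is parsed by stripping the prefix, letter suffix, paralog number
and arm designation. A packaged allowlist of plant species prefixes filters
the registry down to Viridiplantae; it can be overridden by the user.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import edlib
import pandas as pd
from Bio import SeqIO

from ._util import to_rna

__all__ = [
    "ReferenceMature",
    "ConservationCall",
    "default_plant_allowlist",
    "load_reference_matures",
    "reference_stats",
    "scan_conserved",
    "classify_conservation",
    "parse_family",
]

# distance sentinel reported when classifying against an empty reference set
NO_REFERENCE_DISTANCE = 10**9

_FAMILY_RE = re.compile(
    r"^(?P<species>[a-z]{3,4})-(?P<tag>miR|MIR)(?P<number>\d+)"
    r"(?P<letters>[a-z]*)(?:-(?P<paralog>\d+))?(?:-(?P<arm>[53]p))?$",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class ReferenceMature:
    """One registered mature miRNA: id, parsed family, RNA sequence."""

    id: str
    family: str
    sequence: str
    family_parsed: bool = True


@dataclass(frozen=True)
class ConservationCall:
    """Classification of a query sequence against the reference set."""

    query: str
    category: str  # "identical" | "similar" | "novel"
    family: str  # empty iff novel
    distance: int

    def render(self) -> str:
        """Human-readable conservation text for summary tables."""
        if self.category == "identical":
            return f"Identical to {self.family}"
        if self.category == "similar":
            return f"Similar but not identical to {self.family}"
        return "-"


def parse_family(identifier: str) -> tuple[str, bool]:
    """Parse a family label from a miRBase-style mature id.

    "ath-miR168a-5p" -> ("miR168", True). Unparseable ids keep the full id
    as family label and are flagged False.
    """
    token = identifier.split()[0]
    match = _FAMILY_RE.match(token)
    if match is None:
        return token, False
    return f"miR{match.group('number')}", True


def default_plant_allowlist() -> frozenset[str]:
    """Packaged set of 3-letter plant (Viridiplantae) species prefixes."""
    text = resources.files("plantmir.data").joinpath("plant_species.txt").read_text()
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def load_reference_matures(
    path: str | Path, species_allowlist: frozenset[str] | set[str] | None = None
) -> list[ReferenceMature]:
    """Load a mature-miRNA FASTA, keeping species on the allowlist.

    The allowlist holds lowercase 3(-4)-letter species prefixes; records
    whose identifier prefix is not listed are dropped. Returns a list sorted
    by identifier. An empty result is legal (a warning condition for the
    caller, not an error).
    """
    if species_allowlist is None:
        species_allowlist = default_plant_allowlist()
    if not species_allowlist:
        raise ValueError("species allowlist must be non-empty")
    allow = {s.lower() for s in species_allowlist}

    refs: list[ReferenceMature] = []
    for record in SeqIO.parse(str(path), "fasta"):
        prefix = record.id.split("-", 1)[0].lower()
        if prefix not in allow:
            continue
        family, parsed = parse_family(record.id)
        refs.append(
            ReferenceMature(
                id=record.id,
                family=family,
                sequence=to_rna(str(record.seq)),
                family_parsed=parsed,
            )
        )
    refs.sort(key=lambda r: r.id)
    return refs


def reference_stats(refs: list[ReferenceMature]) -> dict[str, int]:
    """Entry / distinct-sequence / distinct-species counts for a registry."""
    return {
        "entries": len(refs),
        "unique_sequences": len({r.sequence for r in refs}),
        "species": len({r.id.split("-", 1)[0].lower() for r in refs}),
    }


def scan_conserved(reads: pd.DataFrame, refs: list[ReferenceMature]) -> pd.DataFrame:
    """Report unique read sequences exactly identical to a reference mature.

    Returns a DataFrame (sequence, families) where ``families`` is the
    sorted, comma-joined list of every matching family; one row per distinct
    read sequence, lexicographic order.
    """
    if not refs:
        raise ValueError("reference set is empty")
    by_seq: dict[str, set[str]] = {}
    for ref in refs:
        by_seq.setdefault(ref.sequence, set()).add(ref.family)
    rows = []
    for seq in sorted(set(reads["sequence"])):
        if seq in by_seq:
            rows.append({"sequence": seq, "families": ",".join(sorted(by_seq[seq]))})
    return pd.DataFrame(rows, columns=["sequence", "families"])


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def classify_conservation(
    query: str, refs: list[ReferenceMature], max_dist: int = 3
) -> ConservationCall:
    """Classify a query against the registry by minimum global edit distance.

    identical (distance 0), similar (1..max_dist) or novel (> max_dist
    against every reference). Ties among equally-near references are broken
    by lexicographically smallest family label.
    """
    if not query:
        raise ValueError("query must be non-empty")
    if not refs:
        return ConservationCall(query, "novel", "", NO_REFERENCE_DISTANCE)

    best_dist = None
    best_family = ""
    for ref in refs:
        dist = _edit_distance(query, ref.sequence)
        if best_dist is None or dist < best_dist or (dist == best_dist and ref.family < best_family):
            best_dist, best_family = dist, ref.family
    if best_dist == 0:
        return ConservationCall(query, "identical", best_family, 0)
    if best_dist <= max_dist:
        return ConservationCall(query, "similar", best_family, best_dist)
    return ConservationCall(query, "novel", "", best_dist)


def write_conservation_table(calls: list[ConservationCall], path: str | Path) -> None:
    """TSV with columns query, category, family, distance."""
    pd.DataFrame(
        [
            {"query": c.query, "category": c.category, "family": c.family, "distance": c.distance}
            for c in calls
        ],
        columns=["query", "category", "family", "distance"],
    ).to_csv(path, sep="\t", index=False)
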