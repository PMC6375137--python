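"""Ingest and pre-treatment of sRNA-seq and degradome-seq libraries.

Reads are collapsed to unique sequences with occurrence counts, filtered to
the plant-sRNA length window (15-40 nt by default), and normalized to RPM
(reads per million) against the number of reads retained after filtering.
Degradome reads are reduced to fixed-length 5' tags (20 nt by default):
longer reads are truncated to their 5' prefix, shorter reads are discarded.

All sequences are uppercased and converted to the RNA alphabet (T -> U) at
ingest; reads containing N are dropped because every downstream mapping step
is exact-match. Collapsed tables are sorted lexicographically by sequence so
that all derived outputs are deterministic.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._util import RNA_ALPHABET, to_rna

__all__ = [
    "Library",
    "load_and_collapse",
    "filter_srna_by_length",
    "normalize_rpm",
    "prepare_degradome_tags",
    "write_expression_table",
]

_ALLOWED_INPUT = frozenset("ACGTUN")


class ParseError(ValueError):
    """A sequencing record could not be parsed or contains illegal symbols."""


class NormalizationError(ValueError):
    """RPM normalization attempted on an empty library."""


@dataclass
class Library:
    """One sequencing library (e.g. one organ) with its RPM denominator.

    ``total_retained`` is the number of reads surviving pre-treatment: the
    post-length-filter read total for sRNA libraries, the retained-tag total
    for degradome libraries.
    """

    library_id: str
    role: str = "srna"  # "srna" or "degradome"
    total_retained: int = 0

    def __post_init__(self) -> None:
        if self.role not in ("srna", "degradome"):
            raise ValueError(f"unknown library role: {self.role!r}")
        if self.total_retained < 0:
            raise ValueError("total_retained must be >= 0")


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_and_collapse(path: str | Path, format: str, library_id: str) -> pd.DataFrame:
    """Read a FASTA/FASTQ file and collapse identical reads.

    Returns a DataFrame with columns ``sequence`` (RNA alphabet, uppercase)
    and ``count``, one row per distinct sequence, sorted lexicographically.
    Reads containing N are dropped; any other non-nucleotide symbol raises
    :class:`ParseError` naming the record index.
    """
    path = Path(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format: {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    counts: dict[str, int] = {}
    with _open_maybe_gzip(path) as handle:
        for idx, record in enumerate(SeqIO.parse(handle, format)):
            raw = str(record.seq).upper()
            if not raw or not set(raw) <= _ALLOWED_INPUT:
                raise ParseError(
                    f"{path.name}: record {idx} ({record.id}) has non-nucleotide symbols"
                )
            if "N" in raw:
                continue
            seq = to_rna(raw)
            counts[seq] = counts.get(seq, 0) + 1

    table = pd.DataFrame(
        {"sequence": sorted(counts), "count": [counts[s] for s in sorted(counts)]}
    )
    if table.empty:
        table = pd.DataFrame({"sequence": pd.Series(dtype=str), "count": pd.Series(dtype=int)})
    table.attrs["library_id"] = library_id
    return table


def filter_srna_by_length(
    reads: pd.DataFrame, min_len: int = 15, max_len: int = 40
) -> tuple[pd.DataFrame, int]:
    """Keep reads with min_len <= length <= max_len (both bounds inclusive).

    Returns the filtered table and the retained read total (the RPM
    denominator for the library).
    """
    if not 1 <= min_len <= max_len:
        raise ValueError(f"invalid length bounds: [{min_len}, {max_len}]")
    if reads.empty:
        out = reads.copy()
        out.attrs.update(reads.attrs)
        return out, 0
    lengths = reads["sequence"].str.len()
    out = reads[(lengths >= min_len) & (lengths <= max_len)].reset_index(drop=True)
    out.attrs.update(reads.attrs)
    return out, int(out["count"].sum())


def normalize_rpm(reads: pd.DataFrame, library: Library) -> pd.DataFrame:
    """Attach an ``rpm`` column: count / total_retained * 1e6.

    Per library the RPM column sums to 1e6 (up to float tolerance) whenever
    total_retained > 0.
    """
    if library.total_retained <= 0:
        raise NormalizationError(
            f"library {library.library_id!r} has no retained reads to normalize against"
        )
    out = reads.copy()
    out["rpm"] = out["count"] / library.total_retained * 1e6
    out.attrs.update(reads.attrs)
    out.attrs["library_id"] = library.library_id
    return out


def prepare_degradome_tags(reads: pd.DataFrame, tag_len: int = 20) -> tuple[pd.DataFrame, int]:
    """Reduce collapsed degradome reads to fixed-length 5' tags.

    Reads longer than ``tag_len`` keep only their 5' ``tag_len``-nt prefix;
    reads shorter than ``tag_len`` are discarded; reads of exactly ``tag_len``
    are kept unchanged. Counts of reads collapsing onto the same tag are
    summed and RPM is recomputed over the retained tags.

    Returns (tag table with columns sequence/count/rpm, retained tag total).
    """
    if tag_len < 1:
        raise ValueError("tag_len must be >= 1")
    tally: dict[str, int] = {}
    for seq, count in zip(reads["sequence"], reads["count"]):
        if len(seq) < tag_len:
            continue
        tag = seq[:tag_len]
        tally[tag] = tally.get(tag, 0) + int(count)
    tags = pd.DataFrame(
        {"sequence": sorted(tally), "count": [tally[t] for t in sorted(tally)]}
    )
    if tags.empty:
        tags = pd.DataFrame({"sequence": pd.Series(dtype=str), "count": pd.Series(dtype=int)})
        tags["rpm"] = pd.Series(dtype=float)
        tags.attrs.update(reads.attrs)
        return tags, 0
    total = int(tags["count"].sum())
    tags["rpm"] = tags["count"] / total * 1e6
    tags.attrs.update(reads.attrs)
    return tags, total


def load_srna_library(
    path: str | Path,
    format: str,
    library_id: str,
    min_len: int = 15,
    max_len: int = 40,
) -> tuple[pd.DataFrame, Library]:
    """Convenience: collapse, length-filter and RPM-normalize one sRNA file."""
    collapsed = load_and_collapse(path, format, library_id)
    filtered, total = filter_srna_by_length(collapsed, min_len, max_len)
    lib = Library(library_id=library_id, role="srna", total_retained=total)
    if total == 0:
        filtered = filtered.assign(rpm=pd.Series(dtype=float))
        return filtered, lib
    return normalize_rpm(filtered, lib), lib


def load_degradome_library(
    path: str | Path, format: str, library_id: str, tag_len: int = 20
) -> tuple[pd.DataFrame, Library]:
    """Convenience: collapse one degradome file and reduce to 5' tags."""
    collapsed = load_and_collapse(path, format, library_id)
    tags, total = prepare_degradome_tags(collapsed, tag_len)
    lib = Library(library_id=library_id, role="degradome", total_retained=total)
    return tags, lib


def merge_libraries(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-library collapsed tables into one wide expression table.

    Output columns: sequence, length, then ``count_<lib>`` and ``rpm_<lib>``
    per library; absent sequences get count 0 / rpm 0. Rows sorted
    lexicographically by sequence.
    """
    all_seqs = sorted(set().union(*[set(t["sequence"]) for t in tables.values()]) if tables else set())
    out = pd.DataFrame({"sequence": all_seqs})
    out["length"] = out["sequence"].str.len() if all_seqs else pd.Series(dtype=int)
    for lib_id, table in tables.items():
        indexed = table.set_index("sequence")
        out[f"count_{lib_id}"] = (
            indexed["count"].reindex(all_seqs).fillna(0).astype(int).to_numpy()
            if all_seqs else pd.Series(dtype=int)
        )
        rpm = indexed["rpm"] if "rpm" in indexed else indexed["count"] * float("nan")
        out[f"rpm_{lib_id}"] = rpm.reindex(all_seqs).fillna(0.0).to_numpy() if all_seqs else pd.Series(dtype=float)
    return out


def write_expression_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a merged expression table as TSV (deterministic row order)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
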