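"""Hairpin precursor discovery from sRNA reads mapped onto assembled transcripts.

The stages mirror how plant miRNA loci present themselves in transcriptome
data: sRNA reads are mapped exactly (both strands, ungapped) onto assembled
transcripts; expression peaks seed candidate precursor windows excised
around them; each window is folded to its minimum-free-energy secondary
structure; and an explicit rule set decides whether the window looks like a
plant pre-miRNA hairpin: a 20-24 nt mature whose star partner is derivable
under the canonical Dicer-like 2-nt 3' overhang geometry, a mostly paired
duplex with limited bulge asymmetry, a precursor within the plant length
range, negative folding energy, and a read signature concentrated on the
two arms. Passing candidates are lifted back to their host transcript with
a 3' extension to become pri-miRNA units for degradome validation.

Coordinates are 1-based with inclusive intervals throughout. Antisense
transcript hits are kept and evaluated in the mapped orientation, since an
assembled transcript may be antisense to the actual miRNA gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import RNA
from Bio import SeqIO

from ._util import intervals_overlap, is_rna, revcomp, to_rna

__all__ = [
    "Transcript",
    "ReadMapping",
    "CandidateWindow",
    "SecondaryStructure",
    "PrecursorCandidate",
    "PriMiRNA",
    "HairpinRules",
    "load_transcripts",
    "map_reads_exact",
    "excise_candidate_windows",
    "fold_sequence",
    "pair_table",
    "derive_star",
    "evaluate_hairpin",
    "assemble_pri_mirna",
    "discover",
]


@dataclass(frozen=True)
class Transcript:
    id: str
    sequence: str  # RNA alphabet


@dataclass(frozen=True)
class ReadMapping:
    """One exact, ungapped placement of a collapsed read on a transcript.

    ``start`` is the 1-based position of the read's 5'-most *transcript*
    coordinate (i.e. the leftmost covered base, on either strand). ``count``
    sums occurrences over all libraries; per-library breakdowns travel in
    ``counts`` and ``rpm``.
    """

    sequence: str
    transcript_id: str
    start: int
    strand: str  # "+" or "-"
    count: int
    counts: tuple[tuple[str, int], ...] = ()
    rpm: tuple[tuple[str, float], ...] = ()

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    @property
    def total_rpm(self) -> float:
        return sum(v for _, v in self.rpm)


@dataclass(frozen=True)
class CandidateWindow:
    transcript_id: str
    start: int
    end: int
    strand: str
    anchor_read: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SecondaryStructure:
    """Dot-bracket MFE structure; mfe in kcal/mol, never positive."""

    dot_bracket: str
    mfe: float


@dataclass
class PrecursorCandidate:
    window: CandidateWindow
    sequence: str  # read-orientation precursor sequence
    structure: SecondaryStructure
    mature5p: tuple[int, int] | None  # precursor coordinates, 1-based inclusive
    mature3p: tuple[int, int] | None
    mature_interval: tuple[int, int] | None  # the read-supported arm
    star_interval: tuple[int, int] | None  # the derived partner arm
    verdict: bool
    fail_reasons: list[str] = field(default_factory=list)
    # summed read-stack count landing on the star interval (+/- 1 nt); used
    # to rank otherwise-equivalent candidates from overlapping windows
    star_support: int = 0

    @property
    def mature_sequence(self) -> str | None:
        if self.mature_interval is None:
            return None
        s, e = self.mature_interval
        return self.sequence[s - 1 : e]

    @property
    def star_sequence(self) -> str | None:
        if self.star_interval is None:
            return None
        s, e = self.star_interval
        return self.sequence[s - 1 : e]

    def arm_sequence(self, arm: str) -> str | None:
        iv = self.mature5p if arm == "5p" else self.mature3p
        if iv is None:
            return None
        return self.sequence[iv[0] - 1 : iv[1]]


@dataclass
class PriMiRNA:
    """A passing precursor in host-transcript context with its 3' extension.

    ``span`` is in transcript coordinates; ``sequence`` and the mature
    intervals are in read orientation, where position 1 is the 5' end of the
    precursor as sequenced (for antisense candidates that is the transcript
    interval reverse-complemented). The extension is always at the 3' end in
    read orientation, so precursor coordinates carry over unchanged.
    """

    pri_id: str
    candidate: PrecursorCandidate
    transcript_id: str
    span: tuple[int, int]
    extension_applied: int
    sequence: str
    dot_bracket: str  # precursor structure padded with '.' over the extension

    @property
    def strand(self) -> str:
        return self.candidate.window.strand

    @property
    def mature5p(self) -> tuple[int, int] | None:
        return self.candidate.mature5p

    @property
    def mature3p(self) -> tuple[int, int] | None:
        return self.candidate.mature3p

    def to_transcript_pos(self, pri_pos: int) -> int:
        """Map a pri coordinate (read orientation) to a transcript coordinate."""
        if self.strand == "+":
            return self.span[0] + pri_pos - 1
        return self.span[1] - pri_pos + 1


def load_transcripts(path: str | Path) -> list[Transcript]:
    """Read assembled transcripts from FASTA (converted to RNA alphabet)."""
    out = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate transcript id: {record.id}")
        seen.add(record.id)
        out.append(Transcript(id=record.id, sequence=to_rna(str(record.seq))))
    return out


def _per_library_columns(row: pd.Series) -> tuple[tuple[tuple[str, int], ...], tuple[tuple[str, float], ...]]:
    counts = tuple(
        (name[len("count_"):], int(row[name])) for name in row.index if name.startswith("count_")
    )
    rpms = tuple(
        (name[len("rpm_"):], float(row[name])) for name in row.index if name.startswith("rpm_")
    )
    return counts, rpms


def map_reads_exact(reads: pd.DataFrame, transcripts: list[Transcript]) -> list[ReadMapping]:
    """Exact, ungapped mapping of collapsed reads to both transcript strands.

    ``reads`` is a collapsed table with a ``sequence`` column and either a
    single ``count`` column or merged per-library ``count_<lib>``/``rpm_<lib>``
    columns. Every occurrence of a read on the sense strand and every
    occurrence of its reverse complement (reported as strand "-") yields one
    record; multi-mapping reads yield one record per locus. Output is sorted
    by (transcript id, start, strand, sequence).
    """
    merged = "count" not in reads.columns
    sense: dict[str, int] = {}
    anti: dict[str, int] = {}
    rows = list(reads.itertuples(index=False))
    for i, row in enumerate(rows):
        sense.setdefault(row.sequence, i)
        anti.setdefault(revcomp(row.sequence), i)
    lengths = sorted({len(r.sequence) for r in rows})

    hits: list[ReadMapping] = []
    for transcript in transcripts:
        seq = transcript.sequence
        n = len(seq)
        for L in lengths:
            for i in range(n - L + 1):
                sub = seq[i : i + L]
                for lookup, strand in ((sense, "+"), (anti, "-")):
                    idx = lookup.get(sub)
                    if idx is None:
                        continue
                    row = reads.iloc[idx]
                    if merged:
                        counts, rpms = _per_library_columns(row)
                        total = sum(c for _, c in counts)
                    else:
                        counts = ((reads.attrs.get("library_id", "lib"), int(row["count"])),)
                        rpms = (
                            ((reads.attrs.get("library_id", "lib"), float(row["rpm"])),)
                            if "rpm" in reads.columns
                            else ()
                        )
                        total = int(row["count"])
                    hits.append(
                        ReadMapping(
                            sequence=str(row["sequence"]),
                            transcript_id=transcript.id,
                            start=i + 1,
                            strand=strand,
                            count=total,
                            counts=counts,
                            rpm=rpms,
                        )
                    )
    hits.sort(key=lambda m: (m.transcript_id, m.start, m.strand, m.sequence))
    return hits


def excise_candidate_windows(
    mappings: list[ReadMapping],
    transcript: Transcript,
    flank: int = 230,
    edge: int = 20,
    peak_window: int = 25,
    min_separation: int = 50,
) -> list[CandidateWindow]:
    """Excise candidate precursor windows around sRNA expression peaks.

    A peak is a read start position whose summed count is maximal within a
    ``peak_window``-nt neighbourhood; peaks are accepted most-abundant first
    and must be >= ``min_separation`` nt apart (per strand). Each peak emits
    two windows — the peak read sitting on the 5' arm ([start - edge,
    read_end + flank]) or on the 3' arm ([start - flank, read_end + edge]) —
    clipped to the transcript; duplicates are removed.
    """
    windows: list[CandidateWindow] = []
    n = len(transcript.sequence)
    for strand in ("+", "-"):
        strand_maps = [m for m in mappings if m.strand == strand and m.transcript_id == transcript.id]
        if not strand_maps:
            continue
        by_start: dict[int, int] = {}
        for m in strand_maps:
            by_start[m.start] = by_start.get(m.start, 0) + m.count
        # local-maximum test within the peak window, then greedy separation
        candidates = [
            s
            for s, c in by_start.items()
            if all(
                by_start.get(other, 0) <= c
                for other in by_start
                if other != s and abs(other - s) < peak_window
            )
        ]
        candidates.sort(key=lambda s: (-by_start[s], s))
        peaks: list[int] = []
        for s in candidates:
            if all(abs(s - p) >= min_separation for p in peaks):
                peaks.append(s)
        for peak_start in peaks:
            at_peak = [m for m in strand_maps if m.start == peak_start]
            anchor = max(at_peak, key=lambda m: (m.count, m.sequence))
            peak_end = peak_start + len(anchor.sequence) - 1
            for w_start, w_end in (
                (peak_start - edge, peak_end + flank),
                (peak_start - flank, peak_end + edge),
            ):
                windows.append(
                    CandidateWindow(
                        transcript_id=transcript.id,
                        start=max(1, w_start),
                        end=min(n, w_end),
                        strand=strand,
                        anchor_read=anchor.sequence,
                    )
                )
    unique = sorted(
        {(w.start, w.end, w.strand): w for w in windows}.values(),
        key=lambda w: (w.start, w.end, w.strand),
    )
    return unique


def fold_sequence(sequence: str) -> SecondaryStructure:
    """Minimum-free-energy fold of an RNA sequence (thermodynamic model).

    Deterministic function of the sequence; returns dot-bracket plus energy
    in kcal/mol. Sequences shorter than 10 nt or outside A/C/G/U raise
    ValueError.
    """
    if len(sequence) < 10:
        raise ValueError("sequence too short to fold (< 10 nt)")
    if not is_rna(sequence):
        raise ValueError("sequence must be over A/C/G/U")
    dot_bracket, mfe = RNA.fold(sequence)
    return SecondaryStructure(dot_bracket=dot_bracket, mfe=round(float(mfe), 2))


def pair_table(dot_bracket: str) -> list[int]:
    """1-based pairing table: table[i] = partner of i, 0 if unpaired.

    Index 0 is a placeholder. Raises ValueError on unbalanced brackets.
    """
    table = [0] * (len(dot_bracket) + 1)
    stack: list[int] = []
    for pos, ch in enumerate(dot_bracket, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            partner = stack.pop()
            table[pos] = partner
            table[partner] = pos
        elif ch != ".":
            raise ValueError(f"illegal structure symbol {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return table


def derive_star(
    structure: SecondaryStructure, mature: tuple[int, int]
) -> tuple[int, int] | None:
    """Derive the star (partner-strand) interval for a mature interval.

    Follows the canonical Dicer-like duplex geometry: each strand's 3' end
    extends 2 nt beyond the last base paired to the other strand. Returns
    None when the mature is mostly unpaired (fewer than half its positions
    paired), spans the terminal loop, or the derived star would overlap the
    mature. The result is clipped to the precursor bounds.
    """
    s, e = mature
    n = len(structure.dot_bracket)
    if not (1 <= s <= e <= n):
        raise ValueError("mature interval outside structure")
    table = pair_table(structure.dot_bracket)
    paired = [i for i in range(s, e + 1) if table[i] != 0]
    if 2 * len(paired) < (e - s + 1):
        return None
    sub = structure.dot_bracket[s - 1 : e]
    if "(" in sub and ")" in sub:  # mature spans the terminal loop
        return None
    # star 3' end: 2 nt past the partner of the mature's 5'-most paired base
    star_end = table[paired[0]] + 2
    # star 5' start: partner of the mature's 3'-most paired base at or before
    # the mature's own 2-nt overhang
    inner = [i for i in paired if i <= e - 2]
    if not inner:
        return None
    star_start = table[inner[-1]]
    star_start, star_end = max(1, star_start), min(n, star_end)
    if star_start >= star_end:
        return None
    if intervals_overlap((star_start, star_end), mature):
        return None
    return (star_start, star_end)


@dataclass(frozen=True)
class HairpinRules:
    """Thresholds for the plant-hairpin rule set (all user-adjustable)."""

    mature_min_len: int = 20
    mature_max_len: int = 24
    max_unpaired_mature: int = 5
    max_asymmetry: int = 3
    max_precursor_len: int = 500
    min_signature_fraction: float = 0.75
    signature_slop: int = 3  # nt of slack around each arm for rule r7


def _to_precursor_coords(m: ReadMapping, window: CandidateWindow) -> tuple[int, int]:
    if window.strand == "+":
        start = m.start - window.start + 1
    else:
        start = window.end - m.end + 1
    return start, start + len(m.sequence) - 1


def evaluate_hairpin(
    window: CandidateWindow,
    sequence: str,
    structure: SecondaryStructure,
    mappings: list[ReadMapping],
    rules: HairpinRules = HairpinRules(),
) -> PrecursorCandidate:
    """Apply the plant-hairpin rule set to a folded candidate window.

    The mature is the most abundant read stack in the window (ties: 5'-most
    start, then lexicographic sequence). Rules, recorded by identifier on
    failure:

    r1  mature length within [20, 24]
    r2  star derivable under the 2-nt 3' overhang duplex geometry
    r3  <= 5 unpaired mature positions within the duplex (3' overhang excluded)
    r4  bulge asymmetry between the two duplex strands <= 3
    r5  precursor length <= 500 nt
    r6  folding energy < 0
    r7  >= 75% of window-mapped read abundance within mature +/- 3 nt,
        star +/- 3 nt, or the loop between them

    A window with no mapped reads fails with reason "no_signature".
    """
    in_window = [
        m
        for m in mappings
        if m.transcript_id == window.transcript_id
        and m.strand == window.strand
        and m.start >= window.start
        and m.end <= window.end
    ]
    if not in_window:
        return PrecursorCandidate(
            window=window,
            sequence=sequence,
            structure=structure,
            mature5p=None,
            mature3p=None,
            mature_interval=None,
            star_interval=None,
            verdict=False,
            fail_reasons=["no_signature"],
        )

    # stack reads by precursor-coordinate placement; the mature is the most
    # abundant stack
    stacks: dict[tuple[int, int, str], int] = {}
    for m in in_window:
        key = (*_to_precursor_coords(m, window), m.sequence)
        stacks[key] = stacks.get(key, 0) + m.count
    (ms, me, _mseq), _ = max(
        stacks.items(), key=lambda kv: (kv[1], -kv[0][0], _lex_inverse(kv[0][2]))
    )
    mature = (ms, me)
    fail: list[str] = []
    table = pair_table(structure.dot_bracket)

    if not rules.mature_min_len <= (me - ms + 1) <= rules.mature_max_len:
        fail.append("r1")

    star = derive_star(structure, mature)
    if star is None:
        fail.append("r2")
    else:
        ss, se = star
        unpaired_mature = sum(1 for i in range(ms, max(ms, me - 2) + 1) if table[i] == 0)
        unpaired_star = sum(1 for i in range(ss, max(ss, se - 2) + 1) if table[i] == 0)
        if unpaired_mature > rules.max_unpaired_mature:
            fail.append("r3")
        if abs(unpaired_mature - unpaired_star) > rules.max_asymmetry:
            fail.append("r4")

    if window.length > rules.max_precursor_len:
        fail.append("r5")
    if not structure.mfe < 0:
        fail.append("r6")

    if star is not None:
        lo = min(ms, star[0]) - rules.signature_slop
        hi = max(me, star[1]) + rules.signature_slop
    else:
        lo, hi = ms - rules.signature_slop, me + rules.signature_slop
    total = sum(stacks.values())
    inside = sum(c for (s, e, _), c in stacks.items() if s >= lo and e <= hi)
    if total == 0 or inside / total < rules.min_signature_fraction:
        fail.append("r7")

    mature5p = mature3p = None
    if star is not None:
        if mature[0] < star[0]:
            mature5p, mature3p = mature, star
        else:
            mature5p, mature3p = star, mature
    else:
        # single-arm annotation: place the mature on the arm it occupies
        db = structure.dot_bracket
        opens = db[: ms - 1].count("(") + db[ms - 1 : me].count("(")
        closes = db[me:].count(")")
        if opens and db[ms - 1 : me].count(")") == 0:
            mature5p = mature
        else:
            mature3p = mature

    star_support = 0
    if star is not None:
        star_support = sum(
            c
            for (s, e, _), c in stacks.items()
            if abs(s - star[0]) <= 1 and abs(e - star[1]) <= 1
        )

    return PrecursorCandidate(
        window=window,
        sequence=sequence,
        structure=structure,
        mature5p=mature5p,
        mature3p=mature3p,
        mature_interval=mature,
        star_interval=star,
        verdict=not fail,
        fail_reasons=fail,
        star_support=star_support,
    )


def _lex_inverse(seq: str) -> tuple[int, ...]:
    # max() tie-break helper: prefer lexicographically smaller sequences
    return tuple(-ord(c) for c in seq)


def window_sequence(window: CandidateWindow, transcript: Transcript) -> str:
    """Window sequence in read orientation (reverse-complemented on strand -)."""
    sub = transcript.sequence[window.start - 1 : window.end]
    return sub if window.strand == "+" else revcomp(sub)


def assemble_pri_mirna(
    candidate: PrecursorCandidate,
    transcript: Transcript,
    extension: int = 20,
    pri_id: str | None = None,
) -> PriMiRNA:
    """Lift a precursor candidate to its pri-miRNA with a 3' extension.

    The extension is applied on the 3' side in read orientation: downstream
    in transcript coordinates for sense candidates, upstream for antisense
    ones. ``extension_applied`` records how many bases were actually
    available on the host transcript.
    """
    w = candidate.window
    n = len(transcript.sequence)
    if w.strand == "+":
        span = (w.start, min(w.end + extension, n))
        applied = span[1] - w.end
    else:
        span = (max(1, w.start - extension), w.end)
        applied = w.start - span[0]
    sub = transcript.sequence[span[0] - 1 : span[1]]
    sequence = sub if w.strand == "+" else revcomp(sub)
    dot_bracket = candidate.structure.dot_bracket + "." * applied
    return PriMiRNA(
        pri_id=pri_id or f"{transcript.id}:{span[0]}-{span[1]}{w.strand}",
        candidate=candidate,
        transcript_id=transcript.id,
        span=span,
        extension_applied=applied,
        sequence=sequence,
        dot_bracket=dot_bracket,
    )


def discover(
    reads: pd.DataFrame,
    transcripts: list[Transcript],
    rules: HairpinRules = HairpinRules(),
    flank: int = 230,
    edge: int = 20,
    extension: int = 20,
    mappings: list[ReadMapping] | None = None,
) -> tuple[list[PrecursorCandidate], list[PriMiRNA]]:
    """Run the full discovery stage: map, excise, fold, evaluate, assemble.

    Returns every evaluated candidate (passing and failing, for diagnostics)
    and the deduplicated passing pri-miRNAs. Windows that localise the same
    mature duplex on the same transcript collapse to a single pri-miRNA (the
    one with the widest window is kept). Precomputed ``mappings`` (from
    :func:`map_reads_exact` on the same inputs) are accepted to avoid
    mapping twice when the caller also needs them.
    """
    if mappings is None:
        mappings = map_reads_exact(reads, transcripts)
    by_transcript: dict[str, list[ReadMapping]] = {}
    for m in mappings:
        by_transcript.setdefault(m.transcript_id, []).append(m)

    candidates: list[PrecursorCandidate] = []
    best: dict[tuple, PrecursorCandidate] = {}
    tx_by_id = {t.id: t for t in transcripts}
    for transcript in transcripts:
        t_maps = by_transcript.get(transcript.id, [])
        if not t_maps:
            continue
        for window in excise_candidate_windows(t_maps, transcript, flank=flank, edge=edge):
            seq = window_sequence(window, transcript)
            if len(seq) < 10:
                continue
            structure = fold_sequence(seq)
            cand = evaluate_hairpin(window, seq, structure, t_maps, rules)
            candidates.append(cand)
            if not cand.verdict:
                continue
            # overlapping windows that localise the same read-supported
            # mature collapse to one locus; prefer the candidate whose star
            # arm is itself covered by reads, then the widest window
            key = (
                window.transcript_id,
                window.strand,
                _lift(cand.mature_interval, window),
            )
            held = best.get(key)
            if held is None or _candidate_rank(cand) > _candidate_rank(held):
                best[key] = cand

    pris = []
    kept = sorted(
        best.values(), key=lambda c: (c.window.transcript_id, c.window.start, c.window.strand)
    )
    for i, cand in enumerate(kept, start=1):
        pris.append(
            assemble_pri_mirna(cand, tx_by_id[cand.window.transcript_id], extension=extension)
        )
    return candidates, pris


def _candidate_rank(cand: PrecursorCandidate) -> tuple[int, int, int]:
    return (cand.star_support, cand.window.length, -cand.window.start)


def _lift(interval: tuple[int, int] | None, window: CandidateWindow) -> tuple[int, int] | None:
    """Precursor interval -> transcript coordinates (orientation-aware)."""
    if interval is None:
        return None
    s, e = interval
    if window.strand == "+":
        return (window.start + s - 1, window.start + e - 1)
    return (window.end - e + 1, window.end - s + 1)
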