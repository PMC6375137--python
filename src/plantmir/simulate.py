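"""Seeded synthetic scenarios: transcripts with planted miRNA hairpins,
sRNA libraries dominated by reads at the planted matures, and degradome
tags whose 5' ends sit at chosen processing sites.

The generator builds each hairpin from the duplex outward: a random mature
5p arm, a 3p arm that is the reverse complement of the 5p duplex core with
a configurable number of mismatches, both placed so the duplex carries the
canonical 2-nt 3' overhangs, joined by a low-complementarity loop and
random flanks. Every draw is confirmed by actually folding the construct
and re-deriving the star arm (and, at scenario level, by running the
discovery stage on clean reads); a draw that does not confirm is retried
with fresh randomness, bounded at 50 attempts. The truth manifest the
scenario carries is therefore guaranteed, not merely intended.

Background degradome reads are sampled away from the planted processing
sites, so a scenario that plants k of the 4 sites yields exactly k
supported sites downstream. All randomness flows from one explicit seed;
regeneration with the same seed and parameters is byte-identical.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._util import revcomp
from .discovery import (
    HairpinRules,
    Transcript,
    derive_star,
    discover,
    fold_sequence,
)

__all__ = [
    "PlantedHairpin",
    "SyntheticScenario",
    "make_synthetic_hairpin",
    "build_scenario",
    "simulate_srna_library",
    "simulate_degradome",
    "write_scenario",
]

_BASES = "ACGU"
_LOOP_BASES = "AC"  # A and C cannot pair with each other: low-complementarity loop


class GenerationError(RuntimeError):
    """Raised when no valid hairpin could be drawn within the retry budget."""


@dataclass(frozen=True)
class PlantedHairpin:
    transcript_id: str
    precursor: tuple[int, int]  # transcript coordinates of the stem-loop construct
    mature5p: tuple[int, int]  # transcript coordinates
    mature3p: tuple[int, int]

    @property
    def sites(self) -> tuple[int, int, int, int]:
        """The four expected processing sites in transcript coordinates."""
        return (
            self.mature5p[0],
            self.mature5p[1] + 1,
            self.mature3p[0],
            self.mature3p[1] + 1,
        )


@dataclass
class SyntheticScenario:
    seed: int
    transcripts: list[Transcript]
    planted: list[PlantedHairpin]
    srna_reads: dict[str, list[str]] = field(default_factory=dict)
    degradome_reads: dict[str, list[str]] = field(default_factory=dict)

    def choose_sites(self, sites_per_pri: int) -> dict[str, tuple[int, ...]]:
        """Per-hairpin choice of which processing sites carry degradome
        signal. Drawn once from the scenario seed, so every library of the
        scenario targets the same sites."""
        rng = random.Random(self.seed * 31 + sites_per_pri)
        return {
            p.transcript_id: tuple(sorted(rng.sample(list(p.sites), k=sites_per_pri)))
            for p in self.planted
        }

    def truth_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "planted": [
                {
                    "transcript_id": p.transcript_id,
                    "precursor": list(p.precursor),
                    "mature5p": list(p.mature5p),
                    "mature3p": list(p.mature3p),
                    "sites": list(p.sites),
                }
                for p in self.planted
            ],
            "srna_libraries": {lib: len(reads) for lib, reads in self.srna_reads.items()},
            "degradome_libraries": {
                lib: len(reads) for lib, reads in self.degradome_reads.items()
            },
        }


def _rng(seed: int | random.Random) -> random.Random:
    return seed if isinstance(seed, random.Random) else random.Random(seed)


def _rand_seq(rng: random.Random, n: int, alphabet: str = _BASES) -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def _close(a: tuple[int, int], b: tuple[int, int], tol: int = 1) -> bool:
    return abs(a[0] - b[0]) <= tol and abs(a[1] - b[1]) <= tol


def make_synthetic_hairpin(
    seed: int | random.Random,
    mature_len: int = 21,
    loop_len: int = 15,
    mismatches: int = 1,
    flank_len: int = 30,
    max_attempts: int = 50,
) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Draw a stem-loop precursor with planted 5p/3p matures.

    Returns (precursor sequence, mature5p, mature3p) with intervals in
    1-based precursor coordinates. The 3p arm is the reverse complement of
    the 5p duplex core (mature minus its 2-nt 3' overhang) with
    ``mismatches`` substitutions, so that folding recovers the duplex with
    2-nt 3' overhangs on both strands. Each draw is fold-confirmed; raises
    GenerationError after ``max_attempts`` failed draws.
    """
    if not 20 <= mature_len <= 24:
        raise ValueError("mature_len must be within [20, 24]")
    if loop_len < 8:
        raise ValueError("loop_len must be >= 8")
    rng = _rng(seed)
    for _ in range(max_attempts):
        m5p = _rand_seq(rng, mature_len)
        core = m5p[: mature_len - 2]
        m3p_core = list(revcomp(core))
        for pos in rng.sample(range(len(m3p_core)), k=min(mismatches, len(m3p_core))):
            m3p_core[pos] = rng.choice([b for b in _BASES if b != m3p_core[pos]])
        m3p = "".join(m3p_core) + _rand_seq(rng, 2, _LOOP_BASES)
        loop = _rand_seq(rng, loop_len, _LOOP_BASES)
        precursor = (
            _rand_seq(rng, flank_len)
            + m5p
            + loop
            + m3p
            + _rand_seq(rng, flank_len)
        )
        iv5 = (flank_len + 1, flank_len + mature_len)
        iv3 = (
            flank_len + mature_len + loop_len + 1,
            flank_len + mature_len + loop_len + len(m3p),
        )
        structure = fold_sequence(precursor)
        if structure.mfe >= 0:
            continue
        star = derive_star(structure, iv5)
        if star is not None and _close(star, iv3):
            return precursor, iv5, iv3
    raise GenerationError(
        f"no foldable hairpin in {max_attempts} attempts (parameters infeasible)"
    )


def _clean_reads(
    transcript: Transcript, hairpin: PlantedHairpin, counts: tuple[int, int] = (10, 10)
) -> pd.DataFrame:
    rows = []
    for iv, count in zip((hairpin.mature5p, hairpin.mature3p), counts):
        rows.append({"sequence": transcript.sequence[iv[0] - 1 : iv[1]], "count": count})
    return pd.DataFrame(rows).sort_values("sequence").reset_index(drop=True)


def _confirmed_transcript(
    rng: random.Random,
    tid: str,
    mature_len: int,
    loop_len: int,
    mismatches: int,
    max_attempts: int = 50,
) -> tuple[Transcript, PlantedHairpin]:
    """Embed a hairpin in random transcript context, confirmed end-to-end.

    Confirmation runs the discovery stage on clean reads at the planted
    matures and requires a passing candidate whose transcript-coordinate
    mature intervals match the truth *exactly*. It is run twice, once with
    each arm as the dominant read stack, because the dominant arm decides
    which windows are excised (hence what sequence context is folded) and
    real libraries may favour either arm.
    """
    for _ in range(max_attempts):
        precursor, iv5, iv3 = make_synthetic_hairpin(
            rng, mature_len=mature_len, loop_len=loop_len, mismatches=mismatches
        )
        ctx5 = _rand_seq(rng, rng.randint(40, 80))
        ctx3 = _rand_seq(rng, rng.randint(40, 80))
        sequence = ctx5 + precursor + ctx3
        off = len(ctx5)
        hairpin = PlantedHairpin(
            transcript_id=tid,
            precursor=(off + 1, off + len(precursor)),
            mature5p=(off + iv5[0], off + iv5[1]),
            mature3p=(off + iv3[0], off + iv3[1]),
        )
        transcript = Transcript(id=tid, sequence=sequence)
        if all(
            _recovers_exactly(transcript, hairpin, counts)
            for counts in ((20, 10), (10, 20))
        ):
            return transcript, hairpin
    raise GenerationError(f"no confirmable transcript for {tid} in {max_attempts} attempts")


def _recovers_exactly(
    transcript: Transcript, hairpin: PlantedHairpin, counts: tuple[int, int]
) -> bool:
    _, pris = discover(_clean_reads(transcript, hairpin, counts), [transcript], HairpinRules())
    for pri in pris:
        if pri.mature5p is None or pri.mature3p is None:
            continue
        got5 = (pri.to_transcript_pos(pri.mature5p[0]), pri.to_transcript_pos(pri.mature5p[1]))
        got3 = (pri.to_transcript_pos(pri.mature3p[0]), pri.to_transcript_pos(pri.mature3p[1]))
        if got5 == hairpin.mature5p and got3 == hairpin.mature3p:
            return True
    return False


def build_scenario(
    seed: int,
    n_hairpins: int = 10,
    n_decoys: int = 2,
    mature_len: int = 21,
    loop_len: int = 15,
    mismatches: int = 1,
) -> SyntheticScenario:
    """Generate transcripts: ``n_hairpins`` with one planted hairpin each,
    plus ``n_decoys`` random hairpin-free transcripts."""
    rng = random.Random(seed)
    transcripts: list[Transcript] = []
    planted: list[PlantedHairpin] = []
    for i in range(n_hairpins):
        transcript, hairpin = _confirmed_transcript(
            rng, f"tc{i + 1:03d}", mature_len, loop_len, mismatches
        )
        transcripts.append(transcript)
        planted.append(hairpin)
    for j in range(n_decoys):
        transcripts.append(
            Transcript(id=f"decoy{j + 1:03d}", sequence=_rand_seq(rng, rng.randint(300, 500)))
        )
    return SyntheticScenario(seed=seed, transcripts=transcripts, planted=planted)


def simulate_srna_library(
    scenario: SyntheticScenario,
    depth: int = 50000,
    signal_fraction: float = 0.8,
    seed: int = 0,
    jitter_prob: float = 0.1,
) -> list[str]:
    """Draw one sRNA library: signal reads at planted matures, background
    reads as random transcript substrings of length 15-40.

    Per hairpin a 5p:3p abundance ratio is drawn once; signal read starts
    jitter by +/- 1 nt with probability ``jitter_prob``. Read multiplicities
    are multinomial at ``depth``. Deterministic under ``seed``.
    """
    if not 0 < signal_fraction <= 1:
        raise ValueError("signal_fraction must be in (0, 1]")
    rng = random.Random(seed)
    tx_by_id = {t.id: t for t in scenario.transcripts}
    frac5p = {id(p): rng.uniform(0.25, 0.75) for p in scenario.planted}
    reads: list[str] = []
    for _ in range(depth):
        if scenario.planted and rng.random() < signal_fraction:
            hp = rng.choice(scenario.planted)
            iv = hp.mature5p if rng.random() < frac5p[id(hp)] else hp.mature3p
            start, end = iv
            if rng.random() < jitter_prob:
                shift = rng.choice((-1, 1))
                start, end = start + shift, end + shift
            seq = tx_by_id[hp.transcript_id].sequence[start - 1 : end]
        else:
            t = rng.choice(scenario.transcripts)
            length = rng.randint(15, 40)
            if length > len(t.sequence):
                length = len(t.sequence)
            start = rng.randint(1, len(t.sequence) - length + 1)
            seq = t.sequence[start - 1 : start + length - 1]
        reads.append(seq)
    return reads


def simulate_degradome(
    scenario: SyntheticScenario,
    sites_per_pri: int = 3,
    depth: int = 2000,
    seed: int = 0,
    signal_fraction: float = 0.9,
) -> list[str]:
    """Draw one degradome library whose signal tags start exactly at
    ``sites_per_pri`` of each planted hairpin's four processing sites.

    Which sites carry signal is decided once per scenario (see
    :meth:`SyntheticScenario.choose_sites`), so multiple libraries of one
    scenario reinforce the same sites rather than covering the complement.
    Background reads (length 20-40) are sampled uniformly but rejected if
    their 5' end falls exactly on any planted processing site, so the number
    of supported sites downstream equals ``sites_per_pri`` by construction.
    Deterministic under ``seed``.
    """
    if not 0 <= sites_per_pri <= 4:
        raise ValueError("sites_per_pri must be within [0, 4]")
    rng = random.Random(seed)
    tx_by_id = {t.id: t for t in scenario.transcripts}
    forbidden = {
        (p.transcript_id, site) for p in scenario.planted for site in p.sites
    }
    chosen: list[tuple[str, int]] = []
    for tid, sites in sorted(scenario.choose_sites(sites_per_pri).items()):
        for site in sites:
            chosen.append((tid, site))

    reads: list[str] = []
    n_signal = int(round(depth * signal_fraction)) if chosen else 0
    for _ in range(n_signal):
        tid, site = rng.choice(chosen)
        seq = tx_by_id[tid].sequence
        length = min(rng.randint(20, 30), len(seq) - site + 1)
        if length < 20:
            continue
        reads.append(seq[site - 1 : site + length - 1])
    for _ in range(depth - n_signal):
        for _attempt in range(100):
            t = rng.choice(scenario.transcripts)
            length = rng.randint(20, 40)
            if length > len(t.sequence):
                continue
            start = rng.randint(1, len(t.sequence) - length + 1)
            if (t.id, start) in forbidden:
                continue
            reads.append(t.sequence[start - 1 : start + length - 1])
            break
    return reads


def populate_libraries(
    scenario: SyntheticScenario,
    library_ids: list[str],
    depth: int = 50000,
    signal_fraction: float = 0.8,
    sites_per_pri: int = 3,
    degradome_depth: int = 2000,
    with_degradome: bool = True,
) -> SyntheticScenario:
    """Fill the scenario with one sRNA (and optionally degradome) library
    per id, each on its own seed stream derived from the scenario seed."""
    master = random.Random(scenario.seed + 7919)
    for lib in library_ids:
        srna_seed = master.randrange(2**31)
        deg_seed = master.randrange(2**31)
        scenario.srna_reads[lib] = simulate_srna_library(
            scenario, depth=depth, signal_fraction=signal_fraction, seed=srna_seed
        )
        if with_degradome:
            scenario.degradome_reads[lib] = simulate_degradome(
                scenario, sites_per_pri=sites_per_pri, depth=degradome_depth, seed=deg_seed
            )
    return scenario


def _write_fastq(reads: list[str], path: Path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i + 1}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_scenario(scenario: SyntheticScenario, out_dir: str | Path) -> dict[str, str]:
    """Emit the scenario through real file formats: transcripts FASTA,
    per-library FASTQ (dummy qualities), and a JSON truth manifest.

    Returns a name -> path mapping. Byte-identical for identical scenarios.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    fasta = out / "transcripts.fasta"
    with open(fasta, "w") as fh:
        for t in scenario.transcripts:
            fh.write(f">{t.id}\n{t.sequence}\n")
    paths["transcripts"] = str(fasta)

    for lib, reads in scenario.srna_reads.items():
        p = out / f"srna_{lib}.fastq"
        _write_fastq(reads, p)
        paths[f"srna_{lib}"] = str(p)
    for lib, reads in scenario.degradome_reads.items():
        p = out / f"degradome_{lib}.fastq"
        _write_fastq(reads, p)
        paths[f"degradome_{lib}"] = str(p)

    truth = out / "truth.json"
    truth.write_text(json.dumps(scenario.truth_manifest(), indent=1, sort_keys=True) + "\n")
    paths["truth"] = str(truth)
    return paths
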