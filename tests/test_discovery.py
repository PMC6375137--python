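"""Read mapping, window excision, folding, duplex geometry, hairpin rules."""

import random

import pandas as pd
import pytest

from plantmir._util import revcomp
from plantmir.discovery import (
    CandidateWindow,
    HairpinRules,
    SecondaryStructure,
    Transcript,
    assemble_pri_mirna,
    derive_star,
    discover,
    evaluate_hairpin,
    excise_candidate_windows,
    fold_sequence,
    map_reads_exact,
    pair_table,
    window_sequence,
)
from plantmir.simulate import make_synthetic_hairpin


def reads_table(seqs_counts) -> pd.DataFrame:
    return pd.DataFrame(
        {"sequence": [s for s, _ in seqs_counts], "count": [c for _, c in seqs_counts]}
    )


def brute_force_scan(read: str, transcripts) -> set:
    """Oracle: two-strand exact substring scan."""
    hits = set()
    for t in transcripts:
        for probe, strand in ((read, "+"), (revcomp(read), "-")):
            for i in range(len(t.sequence) - len(probe) + 1):
                if t.sequence[i : i + len(probe)] == probe:
                    hits.add((t.id, i + 1, strand))
    return hits


class TestMapReadsExact:
    def test_sense_hit(self):
        t = Transcript("t", "A" * 10 + "UGGCAUGCAGAGGAGCGCUUG" + "C" * 10)
        read = t.sequence[10:31]
        out = map_reads_exact(reads_table([(read, 1)]), [t])
        assert [(m.transcript_id, m.start, m.strand) for m in out] == [("t", 11, "+")]

    def test_antisense_hit_reports_leftmost_coordinate(self):
        rng = random.Random(2)
        seq = "".join(rng.choice("ACGU") for _ in range(80))
        t = Transcript("t", seq)
        read = revcomp(seq[49:70])  # covers transcript positions 50..70
        out = [m for m in map_reads_exact(reads_table([(read, 1)]), [t]) if m.strand == "-"]
        assert (out[0].transcript_id, out[0].start) == ("t", 50)

    def test_matches_brute_force_on_random_instances(self):
        rng = random.Random(9)
        transcripts = [
            Transcript(f"t{i}", "".join(rng.choice("ACGU") for _ in range(rng.randint(100, 300))))
            for i in range(5)
        ]
        reads = []
        for _ in range(50):
            if rng.random() < 0.5:  # plant half the reads so hits exist
                t = rng.choice(transcripts)
                L = rng.randint(15, 25)
                i = rng.randint(0, len(t.sequence) - L)
                s = t.sequence[i : i + L]
                reads.append(s if rng.random() < 0.5 else revcomp(s))
            else:
                reads.append("".join(rng.choice("ACGU") for _ in range(rng.randint(15, 25))))
        table = reads_table([(s, 1) for s in sorted(set(reads))])
        got = {
            (m.sequence, m.transcript_id, m.start, m.strand)
            for m in map_reads_exact(table, transcripts)
        }
        expect = {
            (r, *hit) for r in set(reads) for hit in brute_force_scan(r, transcripts)
        }
        assert got == expect


class TestExciseWindows:
    def single_peak_maps(self, t, start=100, length=22, count=50):
        read = t.sequence[start - 1 : start - 1 + length]
        return map_reads_exact(reads_table([(read, count)]), [t])

    def test_window_arithmetic(self):
        rng = random.Random(4)
        t = Transcript("t", "".join(rng.choice("ACGU") for _ in range(1000)))
        maps = self.single_peak_maps(t)  # read covers [100, 121]
        windows = excise_candidate_windows(maps, t)
        spans = {(w.start, w.end) for w in windows}
        assert spans == {(80, 351), (1, 141)}

    def test_peak_at_transcript_start_clips_to_one(self):
        rng = random.Random(6)
        t = Transcript("t", "".join(rng.choice("ACGU") for _ in range(400)))
        read = t.sequence[:21]
        maps = [m for m in map_reads_exact(reads_table([(read, 5)]), [t]) if m.start == 1]
        windows = excise_candidate_windows(maps, t)
        assert all(w.start >= 1 and w.end <= 400 for w in windows)
        assert min(w.start for w in windows) == 1

    def test_close_peaks_merge(self):
        rng = random.Random(8)
        seq = "".join(rng.choice("ACGU") for _ in range(600))
        t = Transcript("t", seq)
        big = seq[99:121]  # start 100, 22 nt, count 50
        small = seq[109:131]  # start 110 (10 nt away), count 10
        maps = map_reads_exact(reads_table([(big, 50), (small, 10)]), [t])
        maps = [m for m in maps if m.start in (100, 110)]
        windows = excise_candidate_windows(maps, t)
        # only the more abundant start seeds windows
        assert {(w.start, w.end) for w in windows} == {(80, 351), (1, 141)}


class TestFold:
    def test_unpairable_sequence(self):
        s = fold_sequence("AAAAAAAAAA")
        assert s.dot_bracket == "." * 10 and s.mfe == 0.0

    def test_simple_hairpin(self):
        s = fold_sequence("GGGGAAAACCCC")
        assert s.dot_bracket.count("(") >= 3 and s.mfe < 0

    def test_random_folds_balanced_and_length_preserving(self):
        rng = random.Random(12)
        for _ in range(5):
            seq = "".join(rng.choice("ACGU") for _ in range(200))
            s = fold_sequence(seq)
            assert len(s.dot_bracket) == 200 and s.mfe <= 0
            pair_table(s.dot_bracket)  # raises if unbalanced

    @pytest.mark.parametrize("bad", ["ACGUACG", "ACGTACGTACGT", "ACGUACGUNN"])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            fold_sequence(bad)


class TestDeriveStar:
    def test_perfect_duplex_hand_table(self):
        # 21-bp perfect stem, 15-nt loop: position i pairs with 58 - i
        db = "(" * 21 + "." * 15 + ")" * 21
        structure = SecondaryStructure(dot_bracket=db, mfe=-30.0)
        star = derive_star(structure, (1, 21))
        # partner(19) = 39; partner(1) + 2 = 59 clipped to 57
        assert star == (39, 57)

    def test_constructed_hairpin_recovers_planted_star(self):
        precursor, iv5, iv3 = make_synthetic_hairpin(11, mismatches=0)
        structure = fold_sequence(precursor)
        assert derive_star(structure, iv5) == iv3
        assert derive_star(structure, iv3) == iv5

    def test_mature_spanning_loop_absent(self):
        db = "(" * 21 + "." * 15 + ")" * 21
        structure = SecondaryStructure(dot_bracket=db, mfe=-30.0)
        assert derive_star(structure, (15, 40)) is None

    def test_unpaired_mature_absent(self):
        db = "(" * 10 + "." * 30 + ")" * 10
        structure = SecondaryStructure(dot_bracket=db, mfe=-5.0)
        assert derive_star(structure, (12, 35)) is None


def planted_transcript(seed=21, mismatches=1):
    precursor, iv5, iv3 = make_synthetic_hairpin(seed, mismatches=mismatches)
    return Transcript("tx", precursor), iv5, iv3


class TestEvaluateHairpin:
    def evaluate(self, t, reads, window=None):
        maps = map_reads_exact(reads, [t])
        window = window or CandidateWindow("tx", 1, len(t.sequence), "+", maps[0].sequence)
        seq = window_sequence(window, t)
        return evaluate_hairpin(window, seq, fold_sequence(seq), maps)

    def test_planted_hairpin_passes_with_both_arms(self):
        t, iv5, iv3 = planted_transcript()
        reads = reads_table(
            [(t.sequence[iv5[0] - 1 : iv5[1]], 30), (t.sequence[iv3[0] - 1 : iv3[1]], 20)]
        )
        cand = self.evaluate(t, reads)
        assert cand.verdict and cand.fail_reasons == []
        assert cand.mature5p == iv5 and cand.mature3p == iv3

    def test_loop_spanning_mature_fails_star_rule(self):
        t, iv5, iv3 = planted_transcript()
        loop_read = t.sequence[iv5[1] - 3 : iv5[1] + 18]  # straddles the loop
        cand = self.evaluate(t, reads_table([(loop_read, 10)]))
        assert not cand.verdict and "r2" in cand.fail_reasons

    def test_scattered_background_fails_signature_rule(self):
        t, iv5, iv3 = planted_transcript()
        background = t.sequence[0:21]  # flank read far from the duplex
        reads = reads_table(
            [(t.sequence[iv5[0] - 1 : iv5[1]], 10), (background, 10)]
        )
        cand = self.evaluate(t, reads)
        # 50% of abundance outside mature/star/loop: rule r7 must fire
        assert "r7" in cand.fail_reasons

    def test_no_reads_rejected(self):
        t, *_ = planted_transcript()
        window = CandidateWindow("tx", 1, len(t.sequence), "+", "A" * 21)
        seq = window_sequence(window, t)
        cand = evaluate_hairpin(window, seq, fold_sequence(seq), [])
        assert not cand.verdict and cand.fail_reasons == ["no_signature"]

    def test_deterministic(self):
        t, iv5, iv3 = planted_transcript()
        reads = reads_table([(t.sequence[iv5[0] - 1 : iv5[1]], 30)])
        a = self.evaluate(t, reads)
        b = self.evaluate(t, reads)
        assert (a.verdict, a.fail_reasons, a.mature5p, a.mature3p) == (
            b.verdict, b.fail_reasons, b.mature5p, b.mature3p,
        )

    def test_antisense_candidate_evaluated_in_read_orientation(self):
        t, iv5, iv3 = planted_transcript(seed=33)
        anti = Transcript("tx", revcomp(t.sequence))
        n = len(t.sequence)
        reads = reads_table(
            [(t.sequence[iv5[0] - 1 : iv5[1]], 30), (t.sequence[iv3[0] - 1 : iv3[1]], 20)]
        )
        maps = [m for m in map_reads_exact(reads, [anti]) if m.strand == "-"]
        assert maps, "arm reads must map antisense"
        window = CandidateWindow("tx", 1, n, "-", maps[0].sequence)
        seq = window_sequence(window, anti)
        cand = evaluate_hairpin(window, seq, fold_sequence(seq), maps)
        assert cand.verdict
        assert cand.mature5p == iv5 and cand.mature3p == iv3


class TestAssemblePri:
    def make_candidate(self, t, start, end, strand="+"):
        window = CandidateWindow(t.id, start, end, strand, "A" * 21)
        seq = window_sequence(window, t)
        structure = SecondaryStructure("." * len(seq), 0.0)
        from plantmir.discovery import PrecursorCandidate

        return PrecursorCandidate(
            window=window, sequence=seq, structure=structure,
            mature5p=(1, 21), mature3p=None, mature_interval=(1, 21),
            star_interval=None, verdict=True,
        )

    def test_extension_arithmetic(self):
        rng = random.Random(14)
        t = Transcript("t", "".join(rng.choice("ACGU") for _ in range(400)))
        pri = assemble_pri_mirna(self.make_candidate(t, 101, 300), t, extension=20)
        assert pri.span == (101, 320) and pri.extension_applied == 20
        assert len(pri.sequence) == 220
        assert pri.dot_bracket.endswith("." * 20)

    def test_no_room_for_extension(self):
        rng = random.Random(15)
        t = Transcript("t", "".join(rng.choice("ACGU") for _ in range(300)))
        pri = assemble_pri_mirna(self.make_candidate(t, 101, 300), t, extension=20)
        assert pri.span == (101, 300) and pri.extension_applied == 0

    def test_zero_extension(self):
        rng = random.Random(16)
        t = Transcript("t", "".join(rng.choice("ACGU") for _ in range(300)))
        pri = assemble_pri_mirna(self.make_candidate(t, 50, 200), t, extension=0)
        assert pri.span == (50, 200) and pri.extension_applied == 0

    def test_antisense_extension_toward_lower_coordinates(self):
        rng = random.Random(18)
        t = Transcript("t", "".join(rng.choice("ACGU") for _ in range(400)))
        pri = assemble_pri_mirna(self.make_candidate(t, 101, 300, "-"), t, extension=20)
        assert pri.span == (81, 300) and pri.extension_applied == 20
        assert pri.sequence == revcomp(t.sequence[80:300])


class TestDiscoverEndToEnd:
    def test_planted_duplex_recovered_and_windows_in_bounds(self):
        t, iv5, iv3 = planted_transcript(seed=44)
        reads = reads_table(
            [(t.sequence[iv5[0] - 1 : iv5[1]], 40), (t.sequence[iv3[0] - 1 : iv3[1]], 25)]
        )
        candidates, pris = discover(reads, [t])
        assert all(1 <= c.window.start <= c.window.end <= len(t.sequence) for c in candidates)
        assert all(c.window.length <= 500 for c in candidates)
        assert len(pris) == 1
        pri = pris[0]
        lift = lambda iv: (pri.to_transcript_pos(iv[0]), pri.to_transcript_pos(iv[1]))
        assert lift(pri.mature5p) == iv5 and lift(pri.mature3p) == iv3
        # arm order in precursor coordinates: 5p before loop before 3p
        assert pri.mature5p[1] < pri.mature3p[0]
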