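"""Registry loading, conserved scan, edit-distance classification."""

import random

import pandas as pd
import pytest

from plantmir.conservation import (
    ConservationCall,
    ReferenceMature,
    classify_conservation,
    default_plant_allowlist,
    load_reference_matures,
    parse_family,
    reference_stats,
    scan_conserved,
)


def brute_force_edit_distance(a: str, b: str) -> int:
    """Textbook dynamic-programming global edit distance (unit costs)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def refs_from(pairs) -> list[ReferenceMature]:
    return [ReferenceMature(id=i, family=parse_family(i)[0], sequence=s) for i, s in pairs]


MIRBASE_FIXTURE = [
    ("ath-miR168a-5p", "UCGCUUGGUGCAGGUCGGGAC"),
    ("ath-miR168a-3p", "CCCGCCUUGCAUCAACUGAAU"),
    ("osa-miR528-5p", "UGGAAGGGGCAUGCAGAGGAG"),
    ("zma-miR171a-3p", "UUGAGCCGUGCCAAUAUCACG"),
    ("ath-miR171a-5p", "UAUUGGCCUGGUUCACUCAGA"),
    # non-plant records that the allowlist must exclude
    ("hsa-miR-21-5p", "UAGCUUAUCAGACUGAUGUUGA"),
    ("mmu-miR-155-5p", "UUAAUGCUAAUUGUGAUAGGGGU"),
]


@pytest.fixture()
def registry(write_fasta):
    return write_fasta({i: s for i, s in MIRBASE_FIXTURE}, "mature.fasta")


class TestParseFamily:
    @pytest.mark.parametrize(
        "identifier, family",
        [
            ("ath-miR168a-5p", "miR168"),
            ("osa-miR528-5p", "miR528"),
            ("zma-MIR171b", "miR171"),
            ("gma-miR156q", "miR156"),
            ("ptc-miR396e-3p", "miR396"),
            ("ath-miR5021", "miR5021"),
        ],
    )
    def test_known_patterns(self, identifier, family):
        assert parse_family(identifier) == (family, True)

    def test_unparseable_keeps_full_id(self):
        label, parsed = parse_family("weird_id_17")
        assert label == "weird_id_17" and not parsed


class TestLoadReference:
    def test_allowlist_filters_non_plant(self, registry):
        refs = load_reference_matures(registry)
        assert len(refs) == 5
        assert all(r.id.split("-")[0] in {"ath", "osa", "zma"} for r in refs)

    def test_stats_counts(self, registry):
        refs = load_reference_matures(registry)
        stats = reference_stats(refs)
        assert stats == {"entries": 5, "unique_sequences": 5, "species": 3}

    def test_empty_fasta(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        assert load_reference_matures(p) == []

    def test_empty_allowlist_rejected(self, registry):
        with pytest.raises(ValueError):
            load_reference_matures(registry, species_allowlist=set())

    def test_packaged_allowlist_is_plant_prefixes(self):
        allow = default_plant_allowlist()
        assert {"ath", "osa", "zma", "ptc", "vvi"} <= allow
        assert "hsa" not in allow and "mmu" not in allow


class TestScanConserved:
    def test_planted_references_found(self, registry):
        rng = random.Random(5)
        refs = load_reference_matures(registry)
        planted = [r.sequence for r in refs][:5]
        noise = ["".join(rng.choice("ACGU") for _ in range(21)) for _ in range(100)]
        reads = pd.DataFrame({"sequence": sorted(set(noise + planted) - set())})
        hit = scan_conserved(reads, refs)
        # brute-force set intersection oracle
        assert set(hit.sequence) == set(reads.sequence) & {r.sequence for r in refs}
        assert len(hit) == 5

    def test_identical_read_reports_family(self, registry):
        refs = load_reference_matures(registry)
        reads = pd.DataFrame({"sequence": ["UCGCUUGGUGCAGGUCGGGAC"]})
        hit = scan_conserved(reads, refs)
        assert list(hit.families) == ["miR168"]

    def test_no_match_is_empty(self, registry):
        refs = load_reference_matures(registry)
        hit = scan_conserved(pd.DataFrame({"sequence": ["A" * 21]}), refs)
        assert hit.empty


class TestClassify:
    def test_identical(self, registry):
        refs = load_reference_matures(registry)
        call = classify_conservation("UCGCUUGGUGCAGGUCGGGAC", refs)
        assert call == ConservationCall("UCGCUUGGUGCAGGUCGGGAC", "identical", "miR168", 0)
        assert call.render() == "Identical to miR168"

    def test_similar_two_mismatches(self):
        refs = refs_from([("osa-miR528-5p", "UGGAAGGGGCAUGCAGAGGAG")])
        query = "UGGAAGGGGCAUGCAGAGCAC"  # two substitutions
        assert brute_force_edit_distance(query, refs[0].sequence) == 2
        call = classify_conservation(query, refs)
        assert (call.category, call.family, call.distance) == ("similar", "miR528", 2)
        assert call.render() == "Similar but not identical to miR528"

    def test_novel_when_distance_exceeds_threshold(self):
        refs = refs_from([("ath-miR168a-5p", "GCGCGGGCGCGGGCGCGGGCG")])
        call = classify_conservation("A" * 21, refs)
        assert call.category == "novel" and call.family == ""

    def test_empty_reference_sentinel(self):
        call = classify_conservation("ACGUACGUACGUACGUACGUA", [])
        assert call.category == "novel" and call.distance > 10**6

    def test_tie_broken_by_lexicographic_family(self):
        seq = "UGGAAGGGGCAUGCAGAGGAG"
        refs = refs_from([("osa-miR999-5p", seq[:-1] + "C"), ("ath-miR100-5p", seq[:-1] + "U")])
        call = classify_conservation(seq, refs)
        assert call.family == "miR100" and call.distance == 1

    def test_agrees_with_dp_oracle_on_random_pairs(self):
        rng = random.Random(17)
        from plantmir.conservation import _edit_distance

        for _ in range(500):
            a = "".join(rng.choice("ACGU") for _ in range(rng.randint(15, 25)))
            b = "".join(rng.choice("ACGU") for _ in range(rng.randint(15, 25)))
            assert _edit_distance(a, b) == brute_force_edit_distance(a, b)

    def test_relaxation_monotonicity(self):
        rng = random.Random(23)
        refs = refs_from(
            [(f"ath-miR{100 + i}-5p", "".join(rng.choice("ACGU") for _ in range(21)))
             for i in range(10)]
        )
        for _ in range(50):
            q = "".join(rng.choice("ACGU") for _ in range(21))
            for k in range(1, 6):
                if classify_conservation(q, refs, max_dist=k).category != "novel":
                    assert classify_conservation(q, refs, max_dist=k + 1).category != "novel"

    def test_scan_subset_of_identical_calls(self, registry):
        rng = random.Random(31)
        refs = load_reference_matures(registry)
        seqs = [r.sequence for r in refs[:3]] + [
            "".join(rng.choice("ACGU") for _ in range(21)) for _ in range(20)
        ]
        reads = pd.DataFrame({"sequence": sorted(set(seqs))})
        scanned = set(scan_conserved(reads, refs).sequence)
        identical = {s for s in reads.sequence
                     if classify_conservation(s, refs).category == "identical"}
        assert scanned <= identical
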