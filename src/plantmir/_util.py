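"""Small shared helpers: RNA alphabet handling and interval arithmetic."""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def to_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement in the RNA alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_rna(seq: str) -> bool:
    return bool(seq) and set(seq) <= RNA_ALPHABET


def clip(value: int, lo: int, hi: int) -> int:
    return max(lo, min(hi, value))


def intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """1-based inclusive interval overlap test."""
    return a[0] <= b[1] and b[0] <= a[1]
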