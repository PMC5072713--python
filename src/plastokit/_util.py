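"""Small shared helpers: alphabets, complements, interval arithmetic on circles."""

from __future__ import annotations

DNA_ALPHABET = set("ACGTN")
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMP = str.maketrans("ACGUNacgun", "UGCANugcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return seq.translate(_RNA_COMP)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def validate_dna(seq: str, *, what: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-ACGTN characters: {sorted(bad)}")
    return seq


def circular_interval_length(start: int, end: int, genome_len: int) -> int:
    """Length of a 1-based inclusive interval that may wrap the origin."""
    if start <= end:
        return end - start + 1
    return genome_len - start + 1 + end


def interval_positions(start: int, end: int, genome_len: int):
    """Yield the 1-based positions of a possibly wrapping inclusive interval."""
    if start <= end:
        yield from range(start, end + 1)
    else:
        yield from range(start, genome_len + 1)
        yield from range(1, end + 1)


def circular_contains(start: int, end: int, pos: int) -> bool:
    if start <= end:
        return start <= pos <= end
    return pos >= start or pos <= end
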