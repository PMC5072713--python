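"""Codon usage, RSCU and tRNA decoding coverage.

Relative synonymous codon usage (RSCU) of a codon is its count divided by
the mean count of its synonymous family under the standard genetic code; a
value of 1.0 means no bias within the family.  Stop codons are treated as a
three-member family, matching how plastome codon-usage tables are usually
laid out.  tRNA decoding applies plain anticodon reverse-complement pairing,
with the lysidine exception: a plastid trnI-CAU reads AUA (not AUG), while
trnM/trnfM-CAU read AUG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from Bio.Data import CodonTable

from ._util import dna_to_rna, revcomp_rna

logger = logging.getLogger(__name__)

_BASES = "UCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)

_STANDARD = CodonTable.unambiguous_rna_by_id[1]
#: codon -> amino acid, with '*' for the stop family
GENETIC_CODE = {**_STANDARD.forward_table,
                **{c: "*" for c in _STANDARD.stop_codons}}
#: amino acid -> synonymous family (tuple of codons)
FAMILIES: dict[str, tuple[str, ...]] = {}
for codon in ALL_CODONS:
    FAMILIES.setdefault(GENETIC_CODE[codon], tuple())
FAMILIES = {aa: tuple(c for c in ALL_CODONS if GENETIC_CODE[c] == aa)
            for aa in FAMILIES}

STOP_CODONS = ("UAA", "UAG", "UGA")


@dataclass
class CodonUsageTable:
    """64 codon counts with RSCU and within-family percentages."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        for codon, n in self.counts.items():
            codon = dna_to_rna(codon)
            if codon not in full:
                raise ValueError(f"not a codon: {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for {codon}")
            full[codon] += int(n)
        self.counts = full

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    @property
    def rscu(self) -> dict[str, Optional[float]]:
        return rscu(self)

    @property
    def aa_fraction(self) -> dict[str, Optional[float]]:
        """Percent of each codon within its synonymous family."""
        out = {}
        for family in FAMILIES.values():
            tot = sum(self.counts[c] for c in family)
            for c in family:
                out[c] = 100.0 * self.counts[c] / tot if tot else None
        return out

    def __add__(self, other: "CodonUsageTable") -> "CodonUsageTable":
        return CodonUsageTable({c: self.counts[c] + other.counts[c]
                                for c in ALL_CODONS})


@dataclass
class TrnaGene:
    """A tRNA gene named by amino acid and anticodon, e.g. trnA-UGC."""

    name: str
    anticodon: str
    count: int = 1

    def __post_init__(self) -> None:
        self.anticodon = dna_to_rna(self.anticodon)
        if len(self.anticodon) != 3 or set(self.anticodon) - set("ACGU"):
            raise ValueError(f"{self.name}: invalid anticodon {self.anticodon!r}")


def count_codons(cds_seqs: Iterable[Union[str, tuple[str, str]]]) -> CodonUsageTable:
    """Count codons (start and stop included) over in-frame CDS sequences.

    Accepts plain sequences or ``(gene_id, sequence)`` pairs; DNA input is
    transcribed to the RNA alphabet for reporting.  A sequence whose length
    is not divisible by 3 raises with the offending gene id; codons with
    ambiguous bases are skipped and logged.
    """
    counts: dict[str, int] = {}
    for idx, item in enumerate(cds_seqs):
        gene, seq = item if isinstance(item, tuple) else (f"record{idx + 1}", item)
        seq = dna_to_rna(seq)
        if len(seq) % 3:
            raise ValueError(f"{gene}: CDS length {len(seq)} not divisible by 3")
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            if set(codon) - set("ACGU"):
                logger.warning("%s: skipping ambiguous codon %s at %d", gene, codon, i)
                continue
            counts[codon] = counts.get(codon, 0) + 1
    return CodonUsageTable(counts)


def rscu(table: CodonUsageTable) -> dict[str, Optional[float]]:
    """RSCU per codon; families with zero total are reported as None."""
    out: dict[str, Optional[float]] = {}
    for family in FAMILIES.values():
        tot = sum(table.counts[c] for c in family)
        for c in family:
            out[c] = table.counts[c] * len(family) / tot if tot else None
    return out


def stop_codon_usage(table: CodonUsageTable) -> Optional[dict[str, int]]:
    """Integer percent of each stop codon among stop codons (None if no stops)."""
    tot = sum(table.counts[c] for c in STOP_CODONS)
    if tot == 0:
        return None
    return {c: round(100 * table.counts[c] / tot) for c in STOP_CODONS}


def decoded_codon(trna: TrnaGene) -> str:
    """The codon a tRNA reads: reverse complement of the anticodon (RNA),
    with the lysidine exception for plastid trnI-CAU (reads AUA)."""
    if trna.anticodon == "CAU":
        base = trna.name.split("-")[0].lower()
        if "trni" in base:
            return "AUA"        # lysidine-modified C34 pairs with A
        return "AUG"            # trnM / trnfM
    return revcomp_rna(trna.anticodon)


def trna_decoding_coverage(trnas: Sequence[TrnaGene]) -> set[str]:
    """Distinct codons decodable by a tRNA gene set (duplicates count once)."""
    return {decoded_codon(t) for t in trnas}
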