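"""Pseudogene classification and the binary character matrix.

A locus is classified against an intact reference CDS using four
independent lesion criteria:

  a. at least one stop codon in frame with the predicted coding region;
  b. start codon outside the accepted set (AUG, GUG, AUC) or terminal stop
     missing;
  c. frameshift — the net internal indel length along a global alignment is
     not a multiple of 3 (terminal gaps excluded; the final 5% of the
     reference is ignored so 3' length polymorphism does not trigger);
  d. less than 80% of the reference coding region is covered by the
     alignment (i.e. at least 20% of the CDS is missing).

Any criterion firing makes the locus a pseudogene; a locus with no sequence
at all is absent.  For tracing gene histories, pseudogenes and frameshifts
are coded as absences: the character matrix holds 1 only for intact loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner

from ._util import validate_dna
from .codons import GENETIC_CODE, dna_to_rna

logger = logging.getLogger(__name__)

START_CODONS = ("ATG", "GTG", "ATC")   # observed plastid alternative starts
STOP_CODONS_DNA = ("TAA", "TAG", "TGA")

#: fraction of the reference 3' end excluded from frameshift detection
FRAMESHIFT_3PRIME_EXCLUSION = 0.05
#: minimum aligned reference coverage below which criterion (d) fires
MIN_REFERENCE_COVERAGE = 0.80


@dataclass
class GeneStatus:
    gene: str
    taxon: str
    status: str                       # intact | pseudogene | absent
    criteria: frozenset = frozenset()
    observed_len: int = 0
    reference_len: int = 0

    def __post_init__(self) -> None:
        if self.status not in ("intact", "pseudogene", "absent"):
            raise ValueError(f"bad status {self.status!r}")
        self.criteria = frozenset(self.criteria)
        if (self.status == "pseudogene") != bool(self.criteria):
            raise ValueError("status 'pseudogene' iff criteria non-empty")

    @property
    def functional(self) -> bool:
        return self.status == "intact"


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    # terminal gaps are free: they are missing coverage (criterion d),
    # not indels (criterion c)
    aligner.end_gap_score = 0
    return aligner


def _internal_stop(observed: str) -> bool:
    """Stop codon strictly before the final codon, reading frame 0."""
    n_codons = len(observed) // 3
    for i in range(n_codons - 1):
        codon = dna_to_rna(observed[3 * i:3 * i + 3])
        if GENETIC_CODE.get(codon) == "*":
            return True
    return False


def classify_gene(observed: Optional[str], reference: str,
                  gene: str = "", taxon: str = "") -> GeneStatus:
    """Classify an observed locus sequence against its reference CDS.

    ``observed is None`` means no locus was found (absent).  The reference
    must be a valid in-frame CDS ending in a stop codon.
    """
    reference = validate_dna(reference, what=f"reference CDS {gene or '?'}")
    if len(reference) % 3:
        raise ValueError(f"{gene}: reference length {len(reference)} not divisible by 3")
    if reference[-3:] not in STOP_CODONS_DNA:
        raise ValueError(f"{gene}: reference CDS lacks a terminal stop codon")
    if observed is None:
        return GeneStatus(gene=gene, taxon=taxon, status="absent",
                          reference_len=len(reference))
    observed = validate_dna(observed, what=f"observed locus {gene or '?'}")

    criteria = set()
    if _internal_stop(observed):
        criteria.add("a")
    if observed[:3] not in START_CODONS or observed[-3:] not in STOP_CODONS_DNA:
        criteria.add("b")

    aligner = _make_aligner()
    aln = aligner.align(reference, observed)[0]
    t_blocks, q_blocks = aln.aligned  # aligned segments (0-based half-open)

    ref_len = len(reference)
    covered = int(sum(e - s for s, e in t_blocks))
    if covered < MIN_REFERENCE_COVERAGE * ref_len:
        criteria.add("d")

    cutoff = (1.0 - FRAMESHIFT_3PRIME_EXCLUSION) * ref_len
    net = 0
    for i in range(len(t_blocks) - 1):
        ref_pos = t_blocks[i][1]          # reference coordinate of the indel
        if ref_pos > cutoff:
            continue
        deleted = t_blocks[i + 1][0] - t_blocks[i][1]
        inserted = q_blocks[i + 1][0] - q_blocks[i][1]
        net += inserted - deleted
    if net % 3:
        criteria.add("c")

    status = "pseudogene" if criteria else "intact"
    return GeneStatus(gene=gene, taxon=taxon, status=status,
                      criteria=frozenset(criteria),
                      observed_len=len(observed), reference_len=ref_len)


# ---------------------------------------------------------------------------
# Character matrix
# ---------------------------------------------------------------------------

@dataclass
class CharacterMatrix:
    """Binary gene-presence matrix: 1 = functional, 0 = pseudogene/absent."""

    taxa: list[str]
    characters: list[str]
    states: np.ndarray    # shape (len(taxa), len(characters)), values {0,1}

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.taxa), len(self.characters)):
            raise ValueError("states shape does not match labels")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must be binary")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if len(set(self.characters)) != len(self.characters):
            raise ValueError("duplicate character labels")

    def column(self, character: str) -> dict[str, int]:
        j = self.characters.index(character)
        return {t: int(self.states[i, j]) for i, t in enumerate(self.taxa)}

    def row(self, taxon: str) -> dict[str, int]:
        i = self.taxa.index(taxon)
        return {c: int(self.states[i, j]) for j, c in enumerate(self.characters)}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\t" + "\t".join(self.characters) + "\n")
            for i, t in enumerate(self.taxa):
                fh.write(t + "\t" + "\t".join(str(int(x)) for x in self.states[i]) + "\n")

    def to_nexus(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#NEXUS\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(self.taxa)} NCHAR={len(self.characters)};\n")
            fh.write("  FORMAT DATATYPE=STANDARD SYMBOLS=\"01\" MISSING=?;\n")
            fh.write("  MATRIX\n")
            width = max(len(t) for t in self.taxa) + 2
            for i, t in enumerate(self.taxa):
                row = "".join(str(int(x)) for x in self.states[i])
                fh.write(f"    {t:<{width}}{row}\n")
            fh.write("  ;\nEND;\n")


def build_character_matrix(statuses: Iterable[GeneStatus],
                           taxa_order: Sequence[str],
                           gene_order: Sequence[str],
                           allow_missing: bool = False) -> CharacterMatrix:
    """Assemble the binary matrix from per-(taxon, gene) statuses.

    A cell is 1 iff the status is intact.  Duplicate (taxon, gene) pairs are
    an error; missing pairs are an error unless ``allow_missing`` (then
    treated as absent, with a warning).
    """
    seen: dict[tuple[str, str], GeneStatus] = {}
    for s in statuses:
        key = (s.taxon, s.gene)
        if key in seen:
            raise ValueError(f"duplicate status for {key}")
        seen[key] = s
    states = np.zeros((len(taxa_order), len(gene_order)), dtype=np.int8)
    for i, taxon in enumerate(taxa_order):
        for j, gene in enumerate(gene_order):
            s = seen.get((taxon, gene))
            if s is None:
                if not allow_missing:
                    raise ValueError(f"missing status for ({taxon}, {gene})")
                logger.warning("missing status for (%s, %s): treated as absent",
                               taxon, gene)
                continue
            states[i, j] = 1 if s.functional else 0
    return CharacterMatrix(taxa=list(taxa_order), characters=list(gene_order),
                           states=states)
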