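"""RNA-editing site calling from RNA-seq pileups, and RPKM quantification.

Plastid RNA editing converts C to U (or, more rarely, U back to C) in
transcripts.  Against a plus-strand reference, an edit inside a
minus-strand gene appears as a genomic G->A (C->U in gene orientation).
A site is called when the filtered coverage reaches ``min_cov`` (default
10x, bases with quality below 25 discarded) and the alternate fraction
reaches ``min_alt_fraction`` (default 0.05).  The editing level is the
percentage of edited reads among reads carrying either the edited or the
reference base at the site, i.e. U/(U+C) for a C->U site.

Only primary, uniquely mapped alignments contribute — multi-mappers (NH
tag > 1, or mapping quality 0) are dropped and counted in the log.
Expression is quantified as RPKM = reads * 1e9 / (gene length * total
unique mapped reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pysam

from ._util import dna_to_rna
from .codons import GENETIC_CODE
from .features import GeneFeature, cds_offset, splice
from .structure import PlastomeSeq

logger = logging.getLogger(__name__)

#: how editing levels are measured (recorded in output metadata)
EDITING_LEVEL_DEFINITION = "percent edited reads, U/(U+C) at the site"

_ALLOWED_CIGAR_OPS = {0, 1, 2, 3, 4, 5, 7, 8}   # M I D N S H = X


@dataclass
class PileupColumn:
    position: int                 # 1-based, plus strand
    ref_base: str
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class EditingSite:
    position: int                 # 1-based genomic, plus strand
    gene: Optional[str]
    strand: Optional[str]
    direction: str                # "C->U" or "U->C" in gene orientation
    level: float                  # percent edited
    depth: int
    edited_reads: int
    reference_reads: int
    codon_from: Optional[str] = None
    codon_to: Optional[str] = None
    codon_position: Optional[int] = None
    aa_from: Optional[str] = None
    aa_to: Optional[str] = None
    synonymous: Optional[bool] = None


@dataclass
class ExpressionRecord:
    gene: str
    unique_reads: int
    gene_len: int
    rpkm: float


def _is_unique_primary(read) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if read.has_tag("NH") and read.get_tag("NH") > 1:
        return False
    if read.mapping_quality == 0:
        return False
    return True


def iter_unique_alignments(sam_path):
    """Primary, uniquely mapped records from a SAM file; multi-mappers are
    dropped and counted in the log."""
    dropped = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for read in fh:
            if not _is_unique_primary(read):
                dropped += 1
                continue
            yield read
    if dropped:
        logger.info("dropped %d non-unique/non-primary alignments", dropped)


def build_pileup(alignments, reference: PlastomeSeq,
                 min_base_qual: int = 25) -> list[PileupColumn]:
    """Per-position filtered base counts from aligned reads.

    ``alignments`` is a SAM path or an iterable of pysam records.  Bases
    below ``min_base_qual`` are discarded; deletions and reference skips
    contribute no base call; insertions are ignored.  On a circular
    reference, alignments running past the end wrap to the origin; on a
    linear one they raise.
    """
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        alignments = iter_unique_alignments(alignments)
    L = len(reference)
    counts: dict[int, dict[str, int]] = {}
    for read in alignments:
        ops = {op for op, _ in (read.cigartuples or ())}
        if ops - _ALLOWED_CIGAR_OPS:
            raise ValueError(f"{read.query_name}: unsupported CIGAR operation")
        quals = read.query_qualities
        seq = read.query_sequence
        for qpos, rpos in read.get_aligned_pairs():
            if qpos is None or rpos is None:
                continue            # deletion/skip or insertion
            if quals is not None and quals[qpos] < min_base_qual:
                continue
            base = seq[qpos].upper()
            if base == "N":
                continue
            if rpos >= L:
                if not reference.circular:
                    raise ValueError(f"{read.query_name}: alignment beyond the "
                                     "end of a linear reference")
                rpos %= L
            pos = rpos + 1
            counts.setdefault(pos, {})[base] = counts.get(pos, {}).get(base, 0) + 1
    return [PileupColumn(position=pos, ref_base=reference.sequence[pos - 1],
                         counts=c)
            for pos, c in sorted(counts.items())]


# ---------------------------------------------------------------------------
# Editing-site calling
# ---------------------------------------------------------------------------

def _host_cds(features: Sequence[GeneFeature], pos: int) -> Optional[GeneFeature]:
    for f in features:
        if f.type == "CDS" and f.contains(pos):
            return f
    return None


def call_editing_sites(pileup: Iterable[PileupColumn],
                       features: Sequence[GeneFeature],
                       min_cov: int = 10,
                       min_alt_fraction: float = 0.05,
                       reference: Optional[PlastomeSeq] = None) -> list[EditingSite]:
    """Call C<->U editing sites from a pileup.

    The genomic substitution is resolved against the host gene's strand: a
    G->A column inside a minus-strand CDS is a C->U edit.  Sites outside
    any CDS are still called (from plus-strand C/T columns) with null codon
    fields.  Codon effects are annotated when ``reference`` is given.
    """
    sites = []
    for col in pileup:
        if col.depth < min_cov:
            continue
        host = _host_cds(features, col.position)
        if host is not None and host.in_intron(col.position):
            host = None
        minus = host is not None and host.strand == "-"
        ref = col.ref_base.upper()
        if minus:
            pairs = {"G": ("A", "C->U"), "A": ("G", "U->C")}
        else:
            pairs = {"C": ("T", "C->U"), "T": ("C", "U->C")}
        if ref not in pairs:
            continue
        alt, direction = pairs[ref]
        n_alt = col.counts.get(alt, 0)
        n_ref = col.counts.get(ref, 0)
        other = col.depth - n_alt - n_ref
        if other:
            logger.info("position %d: %d reads with non-C/U substitutions ignored",
                        col.position, other)
        if n_alt == 0 or n_alt + n_ref == 0:
            continue
        if n_alt / (n_alt + n_ref) < min_alt_fraction:
            continue
        site = EditingSite(position=col.position,
                           gene=host.gene if host else None,
                           strand=host.strand if host else None,
                           direction=direction,
                           level=100.0 * n_alt / (n_alt + n_ref),
                           depth=col.depth,
                           edited_reads=n_alt, reference_reads=n_ref)
        if host is not None and reference is not None:
            annotate_codon_effect(site, host, reference)
        sites.append(site)
    return sites


def annotate_codon_effect(site: EditingSite, feature: GeneFeature,
                          plastome: PlastomeSeq) -> EditingSite:
    """Fill the codon fields of a site inside a CDS (spliced coordinates).

    Raises if the site falls in an intron of the feature — such positions
    must be treated as non-CDS by the caller.
    """
    if feature.in_intron(site.position):
        raise ValueError(f"position {site.position} is intronic in {feature.gene}; "
                         "treat as non-CDS")
    offset = cds_offset(feature, site.position, len(plastome))
    if offset is None:
        raise ValueError(f"position {site.position} not in the exons of {feature.gene}")
    spliced = splice(plastome.sequence, feature, plastome.circular)
    codon_idx, within = divmod(offset, 3)
    codon_dna = spliced[3 * codon_idx:3 * codon_idx + 3]
    if len(codon_dna) < 3:
        raise ValueError(f"{feature.gene}: truncated terminal codon at CDS end")
    codon_from = dna_to_rna(codon_dna)
    src, dst = ("C", "U") if site.direction == "C->U" else ("U", "C")
    if codon_from[within] != src:
        raise ValueError(f"{feature.gene} position {site.position}: codon "
                         f"{codon_from} does not carry {src} at offset {within}")
    codon_to = codon_from[:within] + dst + codon_from[within + 1:]
    site.codon_from = codon_from
    site.codon_to = codon_to
    site.codon_position = within + 1
    site.aa_from = GENETIC_CODE[codon_from]
    site.aa_to = GENETIC_CODE[codon_to]
    site.synonymous = site.aa_from == site.aa_to
    return site


# ---------------------------------------------------------------------------
# Expression (RPKM)
# ---------------------------------------------------------------------------

def gene_read_counts(sam_path, features: Sequence[GeneFeature],
                     genome_len: Optional[int] = None) -> tuple[dict[str, int], int]:
    """Unique-read counts per gene and the total number of unique mapped reads.

    A read is assigned to the gene whose exons contain the midpoint of its
    aligned reference span.
    """
    counts = {f.gene: 0 for f in features}
    total = 0
    for read in iter_unique_alignments(sam_path):
        total += 1
        mid0 = (read.reference_start + read.reference_end - 1) // 2
        pos = mid0 % genome_len + 1 if genome_len else mid0 + 1
        for f in features:
            if f.contains(pos):
                counts[f.gene] += 1
                break
    return counts, total


def rpkm_quantify(unique_counts: dict[str, int], gene_lengths: dict[str, int],
                  total_unique: int) -> list[ExpressionRecord]:
    """RPKM per gene: reads * 1e9 / (gene length * total unique reads)."""
    if total_unique <= 0:
        raise ValueError("total_unique must be positive")
    records = []
    for gene, n in unique_counts.items():
        length = gene_lengths[gene]
        if length <= 0:
            raise ValueError(f"{gene}: gene length must be positive")
        records.append(ExpressionRecord(
            gene=gene, unique_reads=n, gene_len=length,
            rpkm=n * 1e9 / (length * total_unique)))
    return records
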