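"""Quadripartite plastome architecture.

Land-plant chloroplast genomes are circular molecules partitioned into a
large single-copy region (LSC), a small single-copy region (SSC) and two
identical inverted repeats (IRb/IRa) separating them.  This module detects
that architecture from sequence alone, computes per-region base composition,
reports the gene context of the four region junctions, and produces a
per-base accounting of what the genome encodes.

Intervals are 1-based inclusive on the plus strand; an interval whose start
exceeds its end wraps the origin of the circular molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from ._util import (circular_contains, circular_interval_length,
                    interval_positions, revcomp, validate_dna)
from .features import GeneFeature


@dataclass
class PlastomeSeq:
    """A plastome sequence with topology flag."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        self.sequence = validate_dna(self.sequence, what=f"plastome {self.id}")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of a 1-based inclusive interval, wrapping if circular."""
        if start <= end:
            return self.sequence[start - 1:end]
        if not self.circular:
            raise ValueError("wrapping interval on a linear sequence")
        return self.sequence[start - 1:] + self.sequence[:end]

    def rotated(self, offset: int) -> "PlastomeSeq":
        """Rotate the origin by ``offset`` bases (circular only)."""
        if not self.circular:
            raise ValueError("cannot rotate a linear sequence")
        off = offset % len(self.sequence)
        return PlastomeSeq(self.id, self.sequence[off:] + self.sequence[:off], True)


@dataclass
class QuadripartitePartition:
    """LSC / IRb / SSC / IRa intervals covering the genome exactly once."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    ir_length: int
    genome_len: int

    def lengths(self) -> dict[str, int]:
        L = self.genome_len
        return {name: circular_interval_length(*iv, L)
                for name, iv in self.regions().items()}

    def regions(self) -> dict[str, tuple[int, int]]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    def region_of(self, pos: int) -> str:
        for name, (a, b) in self.regions().items():
            if circular_contains(a, b, pos):
                return name
        raise ValueError(f"position {pos} outside genome of length {self.genome_len}")

    def validate(self, plastome: Optional[PlastomeSeq] = None,
                 max_mismatch: int = 0) -> None:
        lens = self.lengths()
        if sum(lens.values()) != self.genome_len:
            raise ValueError("partition does not cover the genome exactly once")
        if lens["IRb"] != lens["IRa"] or lens["IRb"] != self.ir_length:
            raise ValueError("IR lengths inconsistent")
        if lens["LSC"] < lens["SSC"]:
            raise ValueError("LSC must be at least as long as SSC")
        if plastome is not None:
            a = plastome.fetch(*self.irb)
            b = plastome.fetch(*self.ira)
            mism = sum(x != y for x, y in zip(a, revcomp(b)))
            if mism > max_mismatch:
                raise ValueError(f"IRa is not the reverse complement of IRb "
                                 f"({mism} mismatches)")


# ---------------------------------------------------------------------------
# Inverted-repeat detection (exact match, k-mer seed and extend)
# ---------------------------------------------------------------------------

def _maximal_inverted_matches(plastome: PlastomeSeq, k: int,
                              min_len: int) -> list[tuple[int, int, int]]:
    """All maximal exact inverted matches as (start1, start2, length), 0-based.

    start2 is the start of the interval whose reverse complement equals the
    sequence at start1.  On circular molecules coordinates are modular.
    """
    S = plastome.sequence
    L = len(S)
    circular = plastome.circular
    if L < k:
        return []
    R = revcomp(S)

    def s_at(i: int) -> str:
        return S[i % L] if circular else S[i]

    def r_at(i: int) -> str:
        return R[i % L] if circular else R[i]

    # index k-mers of S (wrapping ones included when circular)
    index: dict[str, list[int]] = {}
    doubled = S + S[:k - 1] if circular else S
    n_starts = L if circular else L - k + 1
    for i in range(n_starts):
        index.setdefault(doubled[i:i + k], []).append(i)

    r_doubled = R + R[:k - 1] if circular else R
    covered: set[tuple[int, int]] = set()
    matches = []
    for p in range(n_starts):
        hits = index.get(r_doubled[p:p + k])
        if not hits:
            continue
        for i in hits:
            if ((i % L if circular else i), (p % L if circular else p)) in covered:
                continue
            # extend left
            left = 0
            while left < L - k:
                ni, np_ = i - left - 1, p - left - 1
                if not circular and (ni < 0 or np_ < 0):
                    break
                if s_at(ni) != r_at(np_):
                    break
                left += 1
            # extend right
            length = k
            while left + length < L:
                ni, np_ = i + length, p + length
                if not circular and (ni >= L or np_ >= L):
                    break
                if s_at(ni) != r_at(np_):
                    break
                length += 1
            length += left
            si, sp = i - left, p - left
            for t in range(length):
                covered.add(((si + t) % L if circular else si + t,
                             (sp + t) % L if circular else sp + t))
            if length < min_len:
                continue
            start1 = si % L if circular else si
            start2 = (L - sp - length) % L if circular else L - sp - length
            matches.append((start1, start2, length))
    return matches


def _disjoint_on_circle(a: int, b: int, length: int, L: int,
                        circular: bool) -> bool:
    pos_a = {(a + t) % L if circular else a + t for t in range(length)}
    pos_b = {(b + t) % L if circular else b + t for t in range(length)}
    return not (pos_a & pos_b)


def detect_inverted_repeats(plastome: PlastomeSeq, min_ir_len: int = 10_000,
                            k: int = 21) -> Optional[QuadripartitePartition]:
    """Locate the inverted-repeat pair and derive the quadripartite partition.

    Returns the maximal-length pair of disjoint intervals whose sequences are
    exact reverse complements, or ``None`` when no such pair of at least
    ``min_ir_len`` exists (a "no-IR" genome, distinguishable from an error).
    The partition is invariant under rotation of a circular input.
    """
    if min_ir_len < 1:
        raise ValueError("min_ir_len must be >= 1")
    L = len(plastome)
    k = min(k, max(1, min_ir_len // 2))
    candidates = []
    for s1, s2, m in _maximal_inverted_matches(plastome, k, min_ir_len):
        m = min(m, L)
        if s1 == s2:
            continue
        if not _disjoint_on_circle(s1, s2, m, L, plastome.circular):
            continue
        a, b = sorted((s1, s2))
        candidates.append((m, a, b))
    if not candidates:
        return None
    best_len = max(c[0] for c in candidates)
    best = sorted({c for c in candidates if c[0] == best_len})

    def build(m: int, a: int, b: int) -> QuadripartitePartition:
        gap1_start, gap1_len = (a + m) % L, (b - a - m) % L
        gap2_start, gap2_len = (b + m) % L, (a - b - m) % L
        if gap1_len + gap2_len + 2 * m != L:
            raise AssertionError("partition accounting error")
        if gap1_len >= gap2_len:
            lsc, lsc_len = gap1_start, gap1_len
            irb, ssc, ssc_len, ira = b, gap2_start, gap2_len, a
        else:
            lsc, lsc_len = gap2_start, gap2_len
            irb, ssc, ssc_len, ira = a, gap1_start, gap1_len, b

        def iv(start0: int, length: int) -> tuple[int, int]:
            return (start0 % L + 1, (start0 + length - 1) % L + 1)

        return QuadripartitePartition(lsc=iv(lsc, lsc_len), irb=iv(irb, m),
                                      ssc=iv(ssc, ssc_len), ira=iv(ira, m),
                                      ir_length=m, genome_len=L)

    # tie-break: minimal IRb start after rotating the origin to the LSC start
    parts = [build(m, a, b) for m, a, b in best]
    parts.sort(key=lambda p: (p.irb[0] - p.lsc[0]) % L)
    part = parts[0]
    part.validate(plastome)
    return part


# ---------------------------------------------------------------------------
# Region GC
# ---------------------------------------------------------------------------

def region_gc(plastome: PlastomeSeq,
              partition: QuadripartitePartition) -> dict[str, Optional[float]]:
    """GC percentage per region and for the whole genome.

    N bases are excluded from both numerator and denominator; a region made
    entirely of N is reported as ``None``.
    """
    partition.validate()
    out: dict[str, Optional[float]] = {}
    for name, iv in partition.regions().items():
        out[name] = gc_percent(plastome.fetch(*iv))
    out["genome"] = gc_percent(plastome.sequence)
    return out


def gc_percent(seq: str) -> Optional[float]:
    seq = seq.upper()
    n = len(seq) - seq.count("N")
    if n == 0:
        return None
    return 100.0 * (seq.count("G") + seq.count("C")) / n


# ---------------------------------------------------------------------------
# Junction report
# ---------------------------------------------------------------------------

JUNCTIONS = (("LSC", "IRb"), ("IRb", "SSC"), ("SSC", "IRa"), ("IRa", "LSC"))


def _circ_dist_forward(frm: int, to: int, L: int) -> int:
    return (to - frm) % L


def junction_report(partition: QuadripartitePartition,
                    features: Iterable[GeneFeature],
                    window: int = 1000) -> list[dict]:
    """Gene context of the four region junctions.

    For each junction reports features spanning it (with the overlap length
    on either side) and the nearest feature edge on each side within
    ``window`` bp.  An empty feature list yields empty contexts.
    """
    L = partition.genome_len
    regions = partition.regions()
    feats = list(features)
    report = []
    for up, down in JUNCTIONS:
        e = regions[up][1]            # last base of the upstream region
        s = regions[down][0]          # first base of the downstream region
        spanning = []
        nearest_left = None           # (distance, feature) upstream of junction
        nearest_right = None
        for f in feats:
            a, b = f.span
            if circular_contains(a, b, e) and circular_contains(a, b, s):
                left_overlap = _circ_dist_forward(a - 1, e - 1, L) + 1
                right_overlap = _circ_dist_forward(s - 1, b - 1, L) + 1
                spanning.append({"gene": f.gene, "type": f.type,
                                 "overlap_upstream": left_overlap,
                                 "overlap_downstream": right_overlap})
                continue
            d_left = _circ_dist_forward(b - 1, e - 1, L)
            if d_left <= window and (nearest_left is None or d_left < nearest_left[0]):
                nearest_left = (d_left, f)
            d_right = _circ_dist_forward(s - 1, a - 1, L)
            if d_right <= window and (nearest_right is None or d_right < nearest_right[0]):
                nearest_right = (d_right, f)
        report.append({
            "junction": f"{up}/{down}",
            "position": e,
            "spanning": spanning,
            "nearest_upstream": (
                {"gene": nearest_left[1].gene, "distance": nearest_left[0]}
                if nearest_left else None),
            "nearest_downstream": (
                {"gene": nearest_right[1].gene, "distance": nearest_right[0]}
                if nearest_right else None),
        })
    return report


# ---------------------------------------------------------------------------
# Composition summary
# ---------------------------------------------------------------------------

@dataclass
class CompositionSummary:
    """Per-base accounting of the genome into functional categories."""

    bp: dict[str, int]
    genome_len: int

    CATEGORIES = ("CDS", "tRNA", "rRNA", "intron", "pseudogene", "intergenic")

    @property
    def coding_total(self) -> int:
        return self.bp["CDS"] + self.bp["tRNA"] + self.bp["rRNA"]

    def fraction(self, category: str) -> float:
        return self.bp[category] / self.genome_len

    def as_dict(self) -> dict:
        d = {c: self.bp[c] for c in self.CATEGORIES}
        d["coding_total"] = self.coding_total
        d["genome_len"] = self.genome_len
        return d


# precedence: CDS > tRNA > rRNA > intron > pseudogene > intergenic
_PRECEDENCE = {"intergenic": 0, "pseudogene": 1, "intron": 2,
               "rRNA": 3, "tRNA": 4, "CDS": 5}


def composition_summary(features: Iterable[GeneFeature],
                        genome_len: int) -> CompositionSummary:
    """Count every genome position in exactly one category.

    Overlaps are resolved by precedence (CDS highest), so coding categories
    are never diluted by overlapping annotations; overlapping same-category
    features are counted once.
    """
    marks = np.zeros(genome_len, dtype=np.int8)  # 0 == intergenic

    def mark(interval: tuple[int, int], code: int) -> None:
        for pos in interval_positions(interval[0], interval[1], genome_len):
            if marks[pos - 1] < code:
                marks[pos - 1] = code

    for f in features:
        if f.type not in _PRECEDENCE:
            raise ValueError(f"{f.gene}: unknown category {f.type}")
        code = _PRECEDENCE[f.type]
        for exon in f.genomic_exons:
            if not (1 <= exon[0] <= genome_len and 1 <= exon[1] <= genome_len):
                raise ValueError(f"{f.gene}: exon {exon} outside genome")
            mark(exon, code)
        for intron in f.introns():
            mark(intron, _PRECEDENCE["intron"])

    counts = {name: int(np.sum(marks == code)) for name, code in _PRECEDENCE.items()}
    return CompositionSummary(bp=counts, genome_len=genome_len)
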