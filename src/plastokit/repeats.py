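"""Microsatellite (cpSSR) and dispersed-repeat scanning.

The SSR scanner reports maximal perfect tandem runs of 1-6 bp motifs at
per-unit-length copy-number thresholds (defaults: mono >= 7, di/tri >= 4,
tetra/penta/hexa >= 3 copies), merging qualifying runs separated by at most
a configurable number of interrupting bases into compound loci.  Motifs are
reported as canonical classes taking reverse complementarity into account
(the class representative is the lexicographically smallest rotation of the
motif or of its reverse complement), and a run is attributed only to its
smallest period.

The dispersed-repeat scanner reports maximal forward and palindromic repeat
pairs of a minimum length (default 30 bp) within a Hamming-distance budget
(default 3, i.e. >= 90% identity at 30 bp) — pairs not extendable on either
side without exceeding the budget.  Pairs lying entirely inside a single
tandem SSR locus are filtered, as are self-overlapping pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from ._util import revcomp
from .features import GeneFeature
from .structure import PlastomeSeq

logger = logging.getLogger(__name__)

#: minimum copy number per motif length (unit length -> copies)
DEFAULT_SSR_THRESHOLDS = {1: 7, 2: 4, 3: 4, 4: 3, 5: 3, 6: 3}
DEFAULT_COMPOUND_MAX_GAP = 100


@dataclass
class SSRLocus:
    motif: str                      # canonical motif class
    unit_len: int
    copies: int
    start: int                      # 1-based; end may exceed genome length
    end: int                        # when the locus wraps the origin
    length: int
    kind: str = "simple"            # simple | compound
    members: list["SSRLocus"] = field(default_factory=list)
    spacers: list[int] = field(default_factory=list)
    context: Optional[tuple[str, Optional[str]]] = None

    def __post_init__(self) -> None:
        if self.length != self.end - self.start + 1:
            raise ValueError("SSR length inconsistent with coordinates")
        if self.kind == "simple" and self.length != self.unit_len * self.copies:
            raise ValueError("simple SSR length must equal unit_len * copies")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class RepeatPair:
    kind: str                       # forward | palindromic
    pos1: tuple[int, int]           # 1-based inclusive, pos1 starts first
    pos2: tuple[int, int]
    length: int
    mismatches: int

    @property
    def identity(self) -> float:
        return 100.0 * (self.length - self.mismatches) / self.length


def canonical_motif(motif: str) -> str:
    """Smallest string among all rotations of the motif and its revcomp."""
    variants = []
    for m in (motif, revcomp(motif)):
        variants.extend(m[i:] + m[:i] for i in range(len(m)))
    return min(variants)


def _has_smaller_period(motif: str) -> bool:
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return True
    return False


# ---------------------------------------------------------------------------
# SSR scan
# ---------------------------------------------------------------------------

def _maximal_runs(seq: str, unit_len: int, scan_len: int,
                  max_run: int) -> list[tuple[int, int]]:
    """Maximal tandem runs of period ``unit_len`` as (start0, copies).

    Only runs starting within the first ``scan_len`` characters are
    reported; run length is capped at ``max_run`` full units.
    """
    n = len(seq)
    runs = []
    i = 0
    while i < scan_len:
        if i + unit_len > n or "N" in seq[i:i + unit_len]:
            i += 1
            continue
        # extend matched period
        j = i + unit_len
        while j < n and seq[j] == seq[j - unit_len]:
            j += 1
        copies = (j - i) // unit_len
        if copies >= 2:
            copies = min(copies, max_run)
            runs.append((i, copies))
            i = j - unit_len + 1   # next run can start after this period block
        else:
            i += 1
    return runs


def find_ssrs(plastome: PlastomeSeq,
              thresholds: Optional[dict[int, int]] = None,
              compound_max_gap: int = DEFAULT_COMPOUND_MAX_GAP) -> list[SSRLocus]:
    """Scan for microsatellites; returns simple and compound loci sorted by start."""
    thresholds = dict(DEFAULT_SSR_THRESHOLDS if thresholds is None else thresholds)
    S = plastome.sequence
    L = len(S)
    seq = S + S if plastome.circular else S

    simple: list[SSRLocus] = []
    for unit_len in sorted(thresholds):
        min_copies = thresholds[unit_len]
        scan_len = L if plastome.circular else max(0, L - unit_len + 1)
        for start0, copies in _maximal_runs(seq, unit_len, scan_len, L // unit_len):
            motif = seq[start0:start0 + unit_len]
            if _has_smaller_period(motif):
                continue
            if copies < min_copies:
                continue
            if (plastome.circular and start0 == 0
                    and seq[L - 1] == seq[L - 1 + unit_len]):
                # truncated tail of a wrapping run reported from its true start
                continue
            length = unit_len * copies
            simple.append(SSRLocus(motif=canonical_motif(motif), unit_len=unit_len,
                                   copies=copies, start=start0 + 1,
                                   end=start0 + length, length=length))

    simple.sort(key=lambda l: (l.start, l.end))

    # merge into compound loci
    out: list[SSRLocus] = []
    group = []
    for locus in simple:
        if group and locus.start - group[-1].end - 1 <= compound_max_gap:
            group.append(locus)
        else:
            out.extend(_finish_group(group, compound_max_gap))
            group = [locus]
    out.extend(_finish_group(group, compound_max_gap))
    return out


def _finish_group(group: list[SSRLocus], max_gap: int) -> list[SSRLocus]:
    if not group:
        return []
    if len(group) == 1:
        return group
    start, end = group[0].start, max(l.end for l in group)
    spacers = [group[i + 1].start - group[i].end - 1 for i in range(len(group) - 1)]
    return [SSRLocus(motif="+".join(l.motif for l in group),
                     unit_len=group[0].unit_len, copies=sum(l.copies for l in group),
                     start=start, end=end, length=end - start + 1,
                     kind="compound", members=list(group), spacers=spacers)]


# ---------------------------------------------------------------------------
# Dispersed repeats
# ---------------------------------------------------------------------------

def _count_mismatches(a: str, b: str, i: int, j: int, length: int) -> int:
    return sum(a[i + t] != b[j + t] for t in range(length))


def _seed_len(min_len: int, max_mm: int) -> int:
    """Longest exact seed guaranteed inside any qualifying window
    (pigeonhole: max_mm mismatches split a window into max_mm + 1 runs)."""
    return max(4, -(-(min_len - max_mm) // (max_mm + 1)))


def _cluster_windows(a: str, b: str, d: int, starts: list[int], q: int,
                     max_mm: int, min_len: int) -> list[tuple[int, int, int]]:
    """Maximal <=max_mm-mismatch windows on diagonal ``d`` (a-coord minus
    b-coord) around a cluster of exact seed starts (a-coords, sorted).

    The mismatch profile is scanned once across the cluster span plus a
    horizon of max_mm + 1 mismatches on each side; every maximal window is
    bounded by two real mismatches (or the array edge) with exactly max_mm
    mismatches strictly between them.
    """
    xmin = max(0, d)
    xmax = min(len(a), len(b) + d) - 1
    lo, hi = starts[0], starts[-1] + q - 1
    mism = [x for x in range(lo, hi + 1) if a[x] != b[x - d]]
    # walk outward collecting up to max_mm + 1 mismatches each side
    left: list[int] = []
    x = lo - 1
    while x >= xmin and len(left) < max_mm + 1:
        if a[x] != b[x - d]:
            left.append(x)
        x -= 1
    right: list[int] = []
    x = hi + 1
    while x <= xmax and len(right) < max_mm + 1:
        if a[x] != b[x - d]:
            right.append(x)
        x += 1
    bounds = sorted(left) + mism + right
    if len(left) < max_mm + 1:      # reached the array edge going left
        bounds = [xmin - 1] + bounds
    if len(right) < max_mm + 1:
        bounds = bounds + [xmax + 1]
    windows = []
    for t in range(len(bounds) - (max_mm + 1)):
        a0 = bounds[t] + 1
        a1 = bounds[t + max_mm + 1] - 1
        length = a1 - a0 + 1
        if length >= min_len:
            windows.append((a0, a0 - d, length))
    return windows


def find_repeats(plastome: PlastomeSeq, min_len: int = 30,
                 max_mismatch: int = 3,
                 filter_ssr: bool = True) -> list[RepeatPair]:
    """Find maximal forward and palindromic repeat pairs.

    A pair is maximal when it cannot be extended on either side without
    exceeding the mismatch budget.  Self-overlapping pairs and pairs fully
    contained in a single SSR locus are excluded.  The scan is linear (a
    circular molecule is treated at its deposited origin).
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    S = plastome.sequence
    L = len(S)
    q = _seed_len(min_len, max_mismatch)

    index: dict[str, list[int]] = {}
    for i in range(L - q + 1):
        index.setdefault(S[i:i + q], []).append(i)

    found: set[tuple] = set()

    def scan(b: str, kind: str) -> None:
        diag_hits: dict[int, list[int]] = {}
        for j in range(len(b) - q + 1):
            for i in index.get(b[j:j + q], ()):
                if kind == "forward" and i == j:
                    continue
                diag_hits.setdefault(i - j, []).append(i)
        # seeds further apart than this cannot share a window: a gap of g
        # seed-free columns holds >= g // q mismatches
        gap_limit = (max_mismatch + 2) * q
        for d, starts in diag_hits.items():
            starts = sorted(set(starts))
            cluster = [starts[0]]
            clusters = []
            for s in starts[1:]:
                if s - cluster[-1] > gap_limit:
                    clusters.append(cluster)
                    cluster = [s]
                else:
                    cluster.append(s)
            clusters.append(cluster)
            for cl in clusters:
                for sa, sb, length in _cluster_windows(S, b, d, cl, q,
                                                       max_mismatch, min_len):
                    mm = _count_mismatches(S, b, sa, sb, length)
                    if mm > max_mismatch:
                        continue
                    if kind == "forward":
                        p1, p2 = sorted(((sa, sa + length - 1),
                                         (sb, sb + length - 1)))
                    else:
                        s2 = L - sb - length
                        p1, p2 = sorted(((sa, sa + length - 1),
                                         (s2, s2 + length - 1)))
                    if p1 == p2 or p1[1] >= p2[0]:   # identical or overlapping
                        continue
                    found.add((kind, p1, p2, length, mm))

    scan(S, "forward")
    scan(revcomp(S), "palindromic")

    pairs = [RepeatPair(kind=k, pos1=(p1[0] + 1, p1[1] + 1),
                        pos2=(p2[0] + 1, p2[1] + 1), length=n, mismatches=mm)
             for k, p1, p2, n, mm in sorted(found)]

    # drop sub-maximal windows: a pair contained in another pair of the same
    # kind on the same diagonal is not maximal
    pairs = _drop_contained(pairs)

    if filter_ssr:
        loci = find_ssrs(plastome)
        spans = [(l.start, l.end) for l in loci]
        def inside_one_ssr(p: RepeatPair) -> bool:
            for s, e in spans:
                if s <= p.pos1[0] and p.pos1[1] <= e and \
                        s <= p.pos2[0] and p.pos2[1] <= e:
                    return True
            return False
        pairs = [p for p in pairs if not inside_one_ssr(p)]
    return pairs


def _drop_contained(pairs: list[RepeatPair]) -> list[RepeatPair]:
    keep = []
    for p in pairs:
        contained = False
        for qq in pairs:
            if qq is p or qq.kind != p.kind or qq.length <= p.length:
                continue
            if (qq.pos1[0] <= p.pos1[0] and p.pos1[1] <= qq.pos1[1]
                    and qq.pos2[0] <= p.pos2[0] and p.pos2[1] <= qq.pos2[1]
                    and p.pos1[0] - qq.pos1[0] == p.pos2[0] - qq.pos2[0]):
                contained = True
                break
        if not contained:
            keep.append(p)
    return keep


# ---------------------------------------------------------------------------
# Genomic context
# ---------------------------------------------------------------------------

def classify_context(loci: Iterable[SSRLocus],
                     features: Iterable[GeneFeature],
                     genome_len: Optional[int] = None) -> list[SSRLocus]:
    """Assign each locus a context by its midpoint: coding (with the gene
    name), intron, or intergenic.  A locus overlapping two genes is assigned
    by midpoint and the ambiguity logged."""
    feats = list(features)
    out = []
    for locus in loci:
        mid = locus.midpoint
        if genome_len and mid > genome_len:
            mid = (mid - 1) % genome_len + 1
        exonic = [f for f in feats if f.contains(mid)]
        intronic = [f for f in feats if f.in_intron(mid)]
        if len(exonic) > 1:
            logger.info("SSR at %d overlaps %s; assigned to %s by midpoint",
                        mid, [f.gene for f in exonic], exonic[0].gene)
        if exonic:
            locus.context = ("coding", exonic[0].gene)
        elif intronic:
            locus.context = ("intron", intronic[0].gene)
        else:
            locus.context = ("intergenic", None)
        out.append(locus)
    return out
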