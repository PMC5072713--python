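"""Gene feature model and coordinate utilities.

Features follow the GenBank convention: 1-based inclusive intervals on the
plus strand. A feature stores its exons in 5'->3' *gene* orientation (for a
minus-strand gene this is descending genomic order); ``genomic_exons`` gives
them back sorted on the plus strand. Circular features may wrap the origin,
in which case an exon's start exceeds its end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from ._util import circular_interval_length, circular_contains, revcomp

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "pseudogene")


@dataclass
class GeneFeature:
    gene: str
    type: str
    strand: str
    exons: list[tuple[int, int]]
    region: Optional[str] = None
    copies_in_ir: bool = False
    anticodon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"{self.gene}: unknown feature type {self.type!r}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene}: feature needs at least one exon")
        self.exons = [(int(a), int(b)) for a, b in self.exons]
        # normalise exon order to 5'->3' in gene orientation
        non_wrapping = all(a <= b for a, b in self.exons)
        if non_wrapping and len(self.exons) > 1:
            self.exons.sort(key=lambda e: e[0], reverse=self.strand == "-")

    @property
    def genomic_exons(self) -> list[tuple[int, int]]:
        """Exons sorted in ascending plus-strand order."""
        return sorted(self.exons, key=lambda e: e[0])

    def spliced_length(self, genome_len: Optional[int] = None) -> int:
        glen = genome_len or 10 ** 12
        return sum(circular_interval_length(a, b, glen) for a, b in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Outermost genomic interval (assumes non-wrapping feature)."""
        ex = self.genomic_exons
        return ex[0][0], ex[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, in ascending genomic order."""
        ex = self.genomic_exons
        return [(ex[i][1] + 1, ex[i + 1][0] - 1) for i in range(len(ex) - 1)
                if ex[i + 1][0] - ex[i][1] > 1]

    def contains(self, pos: int) -> bool:
        return any(circular_contains(a, b, pos) for a, b in self.exons)

    def in_intron(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in self.introns())

    def with_region(self, region: str) -> "GeneFeature":
        return replace(self, region=region)


def splice(sequence: str, feature: GeneFeature, circular: bool = True) -> str:
    """Spliced, strand-corrected sequence of a feature.

    Exons are concatenated in gene orientation; minus-strand exons are
    reverse complemented so the result reads 5'->3' of the coding strand.
    """
    L = len(sequence)

    def fetch(a: int, b: int) -> str:
        if a <= b:
            return sequence[a - 1:b]
        if not circular:
            raise ValueError(f"{feature.gene}: wrapping exon on a linear sequence")
        return sequence[a - 1:] + sequence[:b]

    parts = []
    for a, b in feature.exons:
        chunk = fetch(a, b)
        parts.append(revcomp(chunk) if feature.strand == "-" else chunk)
    return "".join(parts)


def cds_offset(feature: GeneFeature, pos: int, genome_len: Optional[int] = None) -> Optional[int]:
    """0-based offset of a genomic position within the spliced CDS, or None.

    The offset counts along the coding strand (5'->3' of the gene).
    """
    glen = genome_len or 10 ** 12
    off = 0
    for a, b in feature.exons:
        elen = circular_interval_length(a, b, glen)
        if circular_contains(a, b, pos):
            if a <= b:
                within = pos - a
            else:  # wrapping exon
                within = pos - a if pos >= a else glen - a + pos
            if feature.strand == "-":
                within = elen - 1 - within
            return off + within
        off += elen
    return None


# ---------------------------------------------------------------------------
# GFF3 / tabular IO (restricted to the feature types above)
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, val = item.partition("=")
        out[key.strip()] = val.strip()
    return out


def read_gff3(path) -> list[GeneFeature]:
    """Read gene features from a GFF3 file.

    Rows of the same type sharing a gene name (``gene=`` or ``ID=`` attribute)
    are collected into one multi-exon feature.
    """
    groups: dict[tuple[str, str], dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            _, _, ftype, start, end, _, strand, _, attrs = cols
            if ftype not in FEATURE_TYPES:
                continue
            a = _parse_attributes(attrs)
            gene = a.get("gene") or a.get("ID") or a.get("Parent")
            if gene is None:
                raise ValueError(f"GFF3 row without gene/ID attribute: {line!r}")
            key = (gene, ftype)
            rec = groups.setdefault(key, {"strand": strand, "exons": [],
                                          "anticodon": a.get("anticodon")})
            rec["exons"].append((int(start), int(end)))
    return [GeneFeature(gene=g, type=t, strand=rec["strand"], exons=rec["exons"],
                        anticodon=rec["anticodon"])
            for (g, t), rec in groups.items()]


def write_gff3(features: Iterable[GeneFeature], path, seqid: str,
               source: str = "plastokit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.gene};gene={f.gene}"
            if f.anticodon:
                attrs += f";anticodon={f.anticodon}"
            for a, b in f.genomic_exons:
                fh.write(f"{seqid}\t{source}\t{f.type}\t{a}\t{b}\t.\t{f.strand}\t.\t{attrs}\n")


def read_feature_table(path) -> list[GeneFeature]:
    """Read the 6-column tabular format: gene, type, strand, start, end, exons.

    The final column is either '-' (single exon, use start/end) or a
    comma-separated list of ``start-end`` sub-intervals.
    """
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            gene, ftype, strand, start, end, exon_s = line.split("\t")
            if exon_s in ("-", ""):
                exons = [(int(start), int(end))]
            else:
                exons = [tuple(int(x) for x in part.split("-"))
                         for part in exon_s.split(",")]
            feats.append(GeneFeature(gene=gene, type=ftype, strand=strand, exons=exons))
    return feats


def write_feature_table(features: Iterable[GeneFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\ttype\tstrand\tstart\tend\texons\n")
        for f in features:
            s, e = f.span
            exon_s = ",".join(f"{a}-{b}" for a, b in f.genomic_exons)
            fh.write(f"{f.gene}\t{f.type}\t{f.strand}\t{s}\t{e}\t{exon_s}\n")
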