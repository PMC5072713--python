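"""Seeded synthetic plastomes and RNA-seq alignments with known ground truth.

The generator emits a circular quadripartite genome (LSC + IRb + SSC + IRa,
with IRa the exact reverse complement of IRb) carrying planted
microsatellites, dispersed repeats, genes with optional pseudogene lesions
(in-frame stop, frameshift, 3' truncation, broken start codon) and C<->U
editing sites, plus pre-aligned RNA-seq reads in SAM.  Background sequence
is sampled per region to hit a GC target (mimicking the IR-high / SSC-low
composition of real plastomes) and scrubbed so no unplanned microsatellite
reaches the reporting thresholds; every planted element's coordinates are
recorded in a TruthSet.

All randomness flows from a single integer seed through one numpy
Generator, so identical configurations produce byte-identical outputs.

The default scale (60 kb genome, 20k reads) emulates the statistical
structure of a real plastome study at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from ._util import revcomp
from .features import GeneFeature
from .repeats import DEFAULT_SSR_THRESHOLDS, find_ssrs
from .structure import PlastomeSeq

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")

LESIONS = ("none", "stop", "frameshift", "truncate20", "no_start")


@dataclass
class GeneSpec:
    name: str
    length: int                    # intact CDS length in bp, divisible by 3
    strand: str = "+"
    region: str = "lsc"            # lsc | ssc | irb
    lesion: str = "none"

    def __post_init__(self) -> None:
        if self.length % 3 or self.length < 30:
            raise ValueError(f"{self.name}: CDS length must be >= 30 and divisible by 3")
        if self.lesion not in LESIONS:
            raise ValueError(f"{self.name}: unknown lesion {self.lesion!r}")
        if self.region not in ("lsc", "ssc", "irb"):
            raise ValueError(f"{self.name}: genes can be planted in lsc/ssc/irb")


@dataclass
class EditSpec:
    gene: str
    cds_offset: int                # 0-based nucleotide offset in the spliced CDS
    direction: str = "C->U"        # in gene orientation
    level: float = 50.0            # percent of transcripts edited

    def __post_init__(self) -> None:
        if not 0 < self.level <= 100:
            raise ValueError("editing level must be in (0, 100]")
        if self.direction not in ("C->U", "U->C"):
            raise ValueError("direction must be 'C->U' or 'U->C'")


@dataclass
class SynthesisConfig:
    seed: int = 1
    lsc_len: int = 30_000
    ir_len: int = 10_000
    ssc_len: int = 10_000
    gc: dict = field(default_factory=lambda: {"lsc": 0.36, "irb": 0.43, "ssc": 0.32})
    planted_ssrs: list = field(default_factory=list)    # (motif, copies, region)
    planted_repeats: list = field(default_factory=list)  # (length, kind, mismatches)
    genes: list = field(default_factory=list)           # GeneSpec
    editing: list = field(default_factory=list)         # EditSpec
    expression: dict = field(default_factory=dict)      # gene -> RPKM target
    n_reads: int = 20_000
    read_length: int = 100
    base_quality: int = 38

    def __post_init__(self) -> None:
        for name in ("lsc_len", "ir_len", "ssc_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.genes = [g if isinstance(g, GeneSpec) else GeneSpec(*g)
                      for g in self.genes]
        self.editing = [e if isinstance(e, EditSpec) else EditSpec(*e)
                        for e in self.editing]


def default_config(seed: int = 1) -> SynthesisConfig:
    """The stock study-shaped configuration used by the examples and tests."""
    return SynthesisConfig(
        seed=seed,
        planted_ssrs=[("A", 9, "lsc"), ("T", 8, "lsc"), ("AT", 5, "lsc"),
                      ("C", 7, "ssc"), ("TTC", 4, "lsc"), ("AATG", 3, "ssc")],
        planted_repeats=[(35, "forward", 0), (40, "palindromic", 2),
                         (32, "forward", 1)],
        genes=[GeneSpec("psbX", 300, "+", "lsc", "none"),
               GeneSpec("rpoZ", 600, "-", "lsc", "none"),
               GeneSpec("ndhQ", 450, "+", "ssc", "stop"),
               GeneSpec("ndhZ", 600, "-", "ssc", "frameshift"),
               GeneSpec("ndhY", 450, "+", "ssc", "truncate20"),
               GeneSpec("ycfX", 300, "+", "lsc", "no_start")],
        editing=[EditSpec("psbX", 90, "C->U", 85.0),
                 EditSpec("psbX", 151, "C->U", 15.0),
                 EditSpec("rpoZ", 200, "C->U", 99.0),
                 EditSpec("rpoZ", 301, "U->C", 40.0)],
        expression={"psbX": 40.0, "rpoZ": 40.0, "ndhQ": 5.0, "ndhZ": 5.0,
                    "ndhY": 5.0, "ycfX": 10.0},
    )


@dataclass
class TruthSet:
    """Planted coordinates and attributes for every synthetic element."""

    region_lengths: dict
    ssrs: list = field(default_factory=list)
    repeats: list = field(default_factory=list)
    genes: list = field(default_factory=list)
    editing: list = field(default_factory=list)
    expression: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Background sequence
# ---------------------------------------------------------------------------

def _background(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(_BASES[rng.choice(4, size=length, p=p)])


def _scrub_ssrs(seq: list[str], rng: np.random.Generator,
                protected: Optional[set[int]] = None,
                keep_frame: Optional[tuple[int, int]] = None,
                max_rounds: int = 50) -> None:
    """Break every tandem run reaching the reporting thresholds, in place.

    ``protected`` positions are never touched.  When ``keep_frame`` is a
    (frame_start, frame_end) interval, substitutions keep the codon at the
    touched position from becoming a stop codon (used inside CDS bodies).
    """
    protected = protected or set()
    for _ in range(max_rounds):
        plast = PlastomeSeq("scrub", "".join(seq), circular=False)
        loci = find_ssrs(plast)
        dirty = False
        for locus in loci:
            members = locus.members or [locus]
            for m in members:
                pos = _pick_free(m.start - 1, m.end - 1, protected)
                if pos is None:
                    continue
                dirty = True
                _substitute(seq, pos, rng, keep_frame)
        if not dirty:
            if not loci:
                return
            # every locus fully protected: accept (caller planted it)
            return
    raise RuntimeError("SSR scrubbing did not converge")


def _pick_free(start0: int, end0: int, protected: set[int]) -> Optional[int]:
    """An unprotected position inside [start0, end0], nearest the middle."""
    mid = (start0 + end0) // 2
    for cand in sorted(range(start0, end0 + 1), key=lambda x: abs(x - mid)):
        if cand not in protected:
            return cand
    return None


def _substitute(seq: list[str], pos: int, rng: np.random.Generator,
                keep_frame: Optional[tuple[int, int]]) -> None:
    current = seq[pos]
    options = [b for b in "ACGT" if b != current]
    rng.shuffle(options)
    for b in options:
        seq[pos] = b
        if keep_frame is not None:
            fs, fe = keep_frame
            if fs <= pos < fe:
                ci = fs + 3 * ((pos - fs) // 3)
                if "".join(seq[ci:ci + 3]) in _STOPS:
                    continue
        return
    seq[pos] = current   # no safe substitution; leave as is


# ---------------------------------------------------------------------------
# Gene construction
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + random non-stop codons + TAA, scrubbed of tandem runs."""
    n_mid = length // 3 - 2
    codons = []
    while len(codons) < n_mid:
        codon = "".join(_BASES[rng.integers(0, 4, size=3)])
        if codon not in _STOPS:
            codons.append(codon)
    seq = list("ATG" + "".join(codons) + "TAA")
    _scrub_ssrs(seq, rng, protected=set(range(3)) | set(range(length - 3, length)),
                keep_frame=(0, length - 3))
    return "".join(seq)


def _apply_lesion(cds: str, lesion: str, rng: np.random.Generator) -> str:
    n_codons = len(cds) // 3
    if lesion == "none":
        return cds
    if lesion == "stop":
        i = n_codons // 3            # internal stop around a third of the way in
        return cds[:3 * i] + "TAA" + cds[3 * i + 3:]
    if lesion == "frameshift":
        i = int(len(cds) * 0.4)
        return cds[:i] + cds[i + 1:]  # single-base deletion
    if lesion == "truncate20":
        keep = 3 * int(0.7 * n_codons)
        return cds[:keep]
    if lesion == "no_start":
        return "AAG" + cds[3:]
    raise ValueError(lesion)


def _force_editing_bases(cds: str, edits: list[EditSpec]) -> str:
    """Ensure each editing site carries its pre-edit base on the coding strand,
    without creating an in-frame stop in the unedited CDS."""
    seq = list(cds)
    for e in edits:
        if not 3 <= e.cds_offset < len(cds) - 3:
            raise ValueError(f"{e.gene}: editing offset {e.cds_offset} outside "
                             "the editable CDS body")
        base = "C" if e.direction == "C->U" else "T"
        seq[e.cds_offset] = base
        ci = 3 * (e.cds_offset // 3)
        if "".join(seq[ci:ci + 3]) in _STOPS:
            # adjust a sibling codon position not itself an editing site
            taken = {x.cds_offset for x in edits}
            for off in range(ci, ci + 3):
                if off == e.cds_offset or off in taken:
                    continue
                for b in "ACGT":
                    seq[off] = b
                    if "".join(seq[ci:ci + 3]) not in _STOPS:
                        break
                break
    return "".join(seq)


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

class _Region:
    """A region under construction: background plus planted islands."""

    def __init__(self, name: str, seq: list[str], margin: int = 150):
        self.name = name
        self.seq = seq
        self.margin = margin
        self.cursor = margin
        self.protected: set[int] = set()

    def place(self, payload: str, rng: np.random.Generator,
              guard: Optional[tuple[str, str]] = None) -> int:
        """Overwrite background with ``payload`` at the next free offset;
        returns the 0-based offset within the region."""
        gap = int(rng.integers(self.margin, self.margin + 120))
        start = self.cursor + gap
        end = start + len(payload)
        if end + self.margin > len(self.seq):
            raise ValueError(f"region {self.name} too small for planted elements")
        self.seq[start:end] = list(payload)
        if guard:
            gl, gr = guard
            self.seq[start - 1] = gl
            self.seq[end] = gr
            self.protected.update((start - 1, end))
        self.protected.update(range(start, end))
        self.cursor = end
        return start


def _guard_bases(motif: str, rng: np.random.Generator) -> tuple[str, str]:
    left = rng.permutation([b for b in "ACGT" if b != motif[-1]])[0]
    right = rng.permutation([b for b in "ACGT" if b != motif[0]])[0]
    return str(left), str(right)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_plastome(config: SynthesisConfig
                      ) -> tuple[PlastomeSeq, list[GeneFeature], TruthSet]:
    """Build the synthetic genome, its features and the ground-truth record."""
    rng = np.random.default_rng(config.seed)
    regions = {name: _Region(name, _background(rng, length, config.gc[name]))
               for name, length in (("lsc", config.lsc_len),
                                    ("irb", config.ir_len),
                                    ("ssc", config.ssc_len))}

    truth = TruthSet(region_lengths={"lsc": config.lsc_len, "irb": config.ir_len,
                                     "ssc": config.ssc_len, "ira": config.ir_len})

    # ---- genes -------------------------------------------------------------
    edits_by_gene: dict[str, list[EditSpec]] = {}
    for e in config.editing:
        edits_by_gene.setdefault(e.gene, []).append(e)

    gene_payloads = []   # (spec, reference, observed, region offset)
    for spec in config.genes:
        reference = _random_cds(rng, spec.length)
        reference = _force_editing_bases(reference, edits_by_gene.get(spec.name, []))
        observed = _apply_lesion(reference, spec.lesion, rng)
        # lesions and forced editing bases may have re-created a tandem run
        obs = list(observed)
        prot = set(range(3)) | set(range(len(observed) - 3, len(observed)))
        if spec.lesion == "none":
            prot |= {e.cds_offset for e in edits_by_gene.get(spec.name, [])}
            _scrub_ssrs(obs, rng, protected=prot,
                        keep_frame=(0, len(observed) - 3))
        else:
            _scrub_ssrs(obs, rng, protected=prot)
        observed = "".join(obs)
        if spec.lesion == "none":
            reference = observed
        payload = revcomp(observed) if spec.strand == "-" else observed
        offset = regions[spec.region].place(payload, rng)
        gene_payloads.append((spec, reference, observed, offset))

    # ---- microsatellites ---------------------------------------------------
    ssr_payloads = []
    for motif, copies, region in config.planted_ssrs:
        motif = motif.upper()
        if not 1 <= len(motif) <= 6:
            raise ValueError(f"SSR motif {motif!r} must be 1-6 bp")
        if copies < DEFAULT_SSR_THRESHOLDS[len(motif)]:
            raise ValueError(f"planted SSR {motif}x{copies} below threshold")
        payload = motif * copies
        offset = regions[region].place(payload, rng,
                                       guard=_guard_bases(motif, rng))
        ssr_payloads.append((motif, copies, region, offset))

    # ---- dispersed repeats -------------------------------------------------
    repeat_payloads = []
    for length, kind, mism in config.planted_repeats:
        if kind not in ("forward", "palindromic"):
            raise ValueError(f"unknown repeat kind {kind!r}")
        seg = _background(rng, length, 0.5)
        _scrub_ssrs(seg, rng)
        seg = "".join(seg)
        mate = seg if kind == "forward" else revcomp(seg)
        mate = list(mate)
        sites = rng.choice(length, size=mism, replace=False) if mism else []
        for s in sites:
            mate[s] = str(rng.permutation([b for b in "ACGT" if b != mate[s]])[0])
        off1 = regions["lsc"].place(seg, rng)
        off2 = regions["lsc"].place("".join(mate), rng)
        repeat_payloads.append((kind, length, int(mism), off1, off2))

    # ---- final background scrub (planted islands protected) ---------------
    for region in regions.values():
        _scrub_ssrs(region.seq, rng, protected=region.protected)

    # ---- pin the IR boundaries ---------------------------------------------
    # the inverted-repeat match must stop exactly at the planted edges: the
    # base left of IRb pairs with the base right of IRa (the LSC start, on the
    # circle) and the base right of IRb pairs with the SSC end
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    lsc_seq, ssc_seq = regions["lsc"].seq, regions["ssc"].seq

    def _break_pairing(seq, idx, partner_base, neighbour):
        if seq[idx] == comp[partner_base]:
            options = [b for b in "ACGT"
                       if b != comp[partner_base] and b != neighbour]
            seq[idx] = str(rng.permutation(options)[0])

    _break_pairing(lsc_seq, -1, lsc_seq[0], lsc_seq[-2])
    _break_pairing(ssc_seq, 0, ssc_seq[-1], ssc_seq[1])

    # ---- assembly ----------------------------------------------------------
    lsc = "".join(regions["lsc"].seq)
    irb = "".join(regions["irb"].seq)
    ssc = "".join(regions["ssc"].seq)
    genome = lsc + irb + ssc + revcomp(irb)
    plastome = PlastomeSeq("synthetic", genome, circular=True)

    region_start = {"lsc": 0, "irb": config.lsc_len,
                    "ssc": config.lsc_len + config.ir_len}
    ira_start = config.lsc_len + config.ir_len + config.ssc_len
    L = len(genome)

    features: list[GeneFeature] = []
    for spec, reference, observed, offset in gene_payloads:
        start0 = region_start[spec.region] + offset
        start, end = start0 + 1, start0 + len(observed)
        features.append(GeneFeature(gene=spec.name, type="CDS", strand=spec.strand,
                                    exons=[(start, end)],
                                    region=spec.region.upper(),
                                    copies_in_ir=spec.region == "irb"))
        truth.genes.append({"name": spec.name, "lesion": spec.lesion,
                            "start": start, "end": end, "strand": spec.strand,
                            "region": spec.region, "reference_cds": reference,
                            "observed_cds": observed})
        if spec.region == "irb":   # mirrored copy in IRa
            m_end = L - (start0 - config.lsc_len) - 0
            m_start = m_end - len(observed) + 1
            mirrored = "+" if spec.strand == "-" else "-"
            features.append(GeneFeature(gene=f"{spec.name}_2", type="CDS",
                                        strand=mirrored, exons=[(m_start, m_end)],
                                        region="IRa", copies_in_ir=True))
        for e in edits_by_gene.get(spec.name, []):
            if spec.lesion != "none":
                raise ValueError(f"{spec.name}: editing sites only on intact genes")
            if spec.strand == "+":
                gpos = start + e.cds_offset
            else:
                gpos = end - e.cds_offset
            truth.editing.append({"gene": spec.name, "position": gpos,
                                  "direction": e.direction, "level": e.level,
                                  "strand": spec.strand})

    for motif, copies, region, offset in ssr_payloads:
        start0 = region_start[region] + offset
        truth.ssrs.append({"motif": motif, "copies": copies,
                           "start": start0 + 1,
                           "end": start0 + len(motif) * copies,
                           "unit_len": len(motif), "region": region})

    for kind, length, mism, off1, off2 in repeat_payloads:
        s1 = region_start["lsc"] + off1
        s2 = region_start["lsc"] + off2
        truth.repeats.append({"kind": kind, "length": length, "mismatches": mism,
                              "pos1": (s1 + 1, s1 + length),
                              "pos2": (s2 + 1, s2 + length)})

    truth.expression = dict(config.expression)
    return plastome, features, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(plastome: PlastomeSeq, features: list[GeneFeature],
                   truth: TruthSet, config: SynthesisConfig,
                   sam_path) -> dict:
    """Emit pre-aligned RNA-seq reads as SAM; returns per-site truth counts.

    Reads are sampled uniformly within each gene's exons, in numbers
    proportional to RPKM target x gene length; at each planted editing site
    every covering read carries the edited base with probability level/100.
    """
    rng = np.random.default_rng(config.seed + 777)
    rl = config.read_length
    qual_char = chr(config.base_quality + 33)
    by_gene = {f.gene: f for f in features}

    edits = []
    for e in truth.editing:
        f = by_gene[e["gene"]]
        pos0 = e["position"] - 1
        if f.strand == "+":
            alt = "T" if e["direction"] == "C->U" else "C"
        else:
            alt = "A" if e["direction"] == "C->U" else "G"
        edits.append({"pos0": pos0, "alt": alt, "level": e["level"], **e})

    weights = {}
    for gene, target in config.expression.items():
        if gene not in by_gene:
            raise ValueError(f"expression target for unknown gene {gene!r}")
        weights[gene] = target * by_gene[gene].spliced_length(len(plastome))
    wsum = sum(weights.values())

    records = []
    truth_counts = {e["position"]: {"edited": 0, "total": 0} for e in edits}
    n_emitted = 0
    for gene, w in weights.items():
        f = by_gene[gene]
        start, end = f.span
        glen = end - start + 1
        frag_len = min(rl, glen)
        n_reads = int(round(config.n_reads * w / wsum))
        starts = rng.integers(0, glen - frag_len + 1, size=n_reads)
        for idx, off in enumerate(starts):
            s0 = start - 1 + int(off)
            seq = list(plastome.sequence[s0:s0 + frag_len])
            for e in edits:
                if s0 <= e["pos0"] < s0 + frag_len:
                    truth_counts[e["pos0"] + 1]["total"] += 1
                    if rng.random() * 100.0 < e["level"]:
                        seq[e["pos0"] - s0] = e["alt"]
                        truth_counts[e["pos0"] + 1]["edited"] += 1
            flag = 16 if f.strand == "-" else 0
            records.append((s0 + 1, f"{gene}.{idx}", flag, "".join(seq)))
            n_emitted += 1

    records.sort(key=lambda r: (r[0], r[1]))
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{plastome.id}\tLN:{len(plastome)}\n")
        for pos, name, flag, seq in records:
            fh.write(f"{name}\t{flag}\t{plastome.id}\t{pos}\t60\t{len(seq)}M\t"
                     f"*\t0\t0\t{seq}\t{qual_char * len(seq)}\n")
    return {"n_reads": n_emitted, "per_site": truth_counts}
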