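"""End-to-end orchestration and comparative summaries.

``run_pipeline`` chains the stages — structure detection, codon usage,
SSR/repeat scanning, pseudogene classification, editing/expression, and
gene-history tracing — over one configuration, writing a machine-readable
JSON report plus per-stage TSVs.  The report is a pure function of
(inputs, config, seed) except for its timestamp field.

This module also houses the comparative summaries: the gene-repertoire
(Venn-style) comparison across taxa and the ndh complex span accounting
(total bp occupied by ndh loci, IR-resident genes counted twice, as a
fraction of the plastome).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from . import codons, editing, parsimony, pseudogenes, repeats, structure
from .features import GeneFeature, read_gff3, splice
from .io import read_plastome, write_tsv
from .structure import PlastomeSeq

logger = logging.getLogger(__name__)

#: gene-name normalisation: published spelling variants -> canonical name
GENE_SYNONYMS = {
    "trn(f)m-cau": "trnfM-CAU",
    "trnfm-cau": "trnfM-CAU",
    "rrn4.5s": "rrn4.5",
    "rrn5s": "rrn5",
    "rrn16s": "rrn16",
    "rrn23s": "rrn23",
}


def normalize_gene_name(name: str) -> str:
    key = name.strip().lower()
    return GENE_SYNONYMS.get(key, name.strip())


# ---------------------------------------------------------------------------
# Repertoire comparison
# ---------------------------------------------------------------------------

@dataclass
class RepertoireComparison:
    taxa: list[str]
    gene_sets: dict[str, frozenset]
    core: frozenset
    unique: dict[str, frozenset]
    overlap_counts: dict[tuple[str, ...], int]

    def as_dict(self) -> dict:
        return {
            "taxa": self.taxa,
            "core_size": len(self.core),
            "core": sorted(self.core),
            "unique": {t: sorted(s) for t, s in self.unique.items()},
            "overlap_counts": {"+".join(k): v
                               for k, v in self.overlap_counts.items()},
        }


_RNA_PREFIXES = ("trn", "rrn")


def compare_repertoires(per_taxon: Mapping[str, Iterable[str]],
                        exclude_rna: bool = False) -> RepertoireComparison:
    """Exact set algebra over per-taxon gene repertoires.

    Names are normalised through the synonyms table; duplicates within a
    taxon are collapsed with a warning.  ``exclude_rna`` drops tRNA/rRNA
    genes before comparing.  ``overlap_counts`` gives, for every non-empty
    taxon combination, the number of genes present in exactly those taxa.
    """
    sets: dict[str, frozenset] = {}
    for taxon, genes in per_taxon.items():
        names = [normalize_gene_name(g) for g in genes]
        if exclude_rna:
            names = [n for n in names if not n.lower().startswith(_RNA_PREFIXES)]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            logger.warning("%s: duplicate gene names collapsed: %s", taxon, dupes)
        sets[taxon] = frozenset(names)
    taxa = list(sets)
    core = frozenset.intersection(*sets.values()) if sets else frozenset()
    unique = {t: sets[t] - frozenset().union(*(sets[o] for o in taxa if o != t))
              if len(taxa) > 1 else sets[t]
              for t in taxa}
    all_genes = frozenset().union(*sets.values()) if sets else frozenset()
    membership: dict[tuple[str, ...], int] = {}
    for gene in all_genes:
        combo = tuple(t for t in taxa if gene in sets[t])
        membership[combo] = membership.get(combo, 0) + 1
    return RepertoireComparison(taxa=taxa, gene_sets=sets, core=core,
                                unique=unique, overlap_counts=membership)


# ---------------------------------------------------------------------------
# ndh span accounting
# ---------------------------------------------------------------------------

@dataclass
class NdhSpanReport:
    taxon: str
    rows: list[dict]            # gene, length_bp, status, ir_copies
    total_bp: int
    genome_len: int

    @property
    def fraction(self) -> float:
        return self.total_bp / self.genome_len

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def ndh_span_report(records: Iterable[Mapping], genome_len: int,
                    taxon: str = "") -> NdhSpanReport:
    """Total genomic span of the ndh complex for one taxon.

    Each record carries gene, length_bp, status and ir_copies; IR-resident
    loci are counted once per IR copy.  Absent loci contribute nothing.
    """
    if not genome_len:
        raise ValueError("genome_len is required")
    rows, total = [], 0
    for r in records:
        copies = int(r.get("ir_copies", 1) or 0)
        raw = r.get("length_bp")
        missing = raw is None or raw == "" or raw != raw   # NaN-safe
        length = 0 if missing else int(raw)
        total += length * max(copies, 0)
        rows.append({"gene": r["gene"], "length_bp": length,
                     "status": r.get("status", ""), "ir_copies": copies})
    return NdhSpanReport(taxon=taxon, rows=rows, total_bp=total,
                         genome_len=genome_len)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

_STAGES = ("structure", "codon_usage", "ssr", "repeats", "editing", "trace")


def run_pipeline(config, out_dir) -> dict:
    """Run the configured stages and write report.json plus per-stage TSVs.

    ``config`` is a mapping or a YAML file path with keys: ``genome``
    (FASTA), ``features`` (GFF3), ``sam`` (alignments, for editing),
    ``tree`` (newick) and ``matrix`` (character TSV, for trace),
    ``stages`` (subset of the stage names, default all applicable), and
    optional threshold overrides (``min_ir_len``, ``ssr_thresholds``,
    ``min_repeat_len``, ``max_mismatch``, ``min_cov``, ``min_base_qual``).
    """
    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages") or list(_STAGES)
    report: dict = {
        "config": {k: str(v) for k, v in config.items()},
        "stages": {},
        "editing_level_definition": editing.EDITING_LEVEL_DEFINITION,
        "generated_at": datetime.now(timezone.utc).isoformat(),
    }

    def require(key: str, stage: str):
        if key not in config:
            raise ValueError(f"stage {stage!r} requires config key {key!r}")
        return config[key]

    plastome: Optional[PlastomeSeq] = None
    feats: list[GeneFeature] = []
    if "genome" in config:
        plastome = read_plastome(require("genome", "any"))
    if "features" in config:
        feats = read_gff3(config["features"])

    if "structure" in stages:
        genome = plastome or read_plastome(require("genome", "structure"))
        part = structure.detect_inverted_repeats(
            genome, min_ir_len=int(config.get("min_ir_len", 10_000)))
        if part is None:
            report["stages"]["structure"] = {"partition": None}
        else:
            gc = structure.region_gc(genome, part)
            comp = structure.composition_summary(feats, len(genome))
            junctions = structure.junction_report(part, feats)
            report["stages"]["structure"] = {
                "partition": {name: list(iv) for name, iv in part.regions().items()},
                "ir_length": part.ir_length,
                "region_lengths": part.lengths(),
                "gc_percent": {k: (round(v, 2) if v is not None else None)
                               for k, v in gc.items()},
                "composition": comp.as_dict(),
                "junctions": junctions,
            }

    if "codon_usage" in stages:
        genome = plastome or read_plastome(require("genome", "codon_usage"))
        cds = [(f.gene, splice(genome.sequence, f, genome.circular))
               for f in feats if f.type == "CDS"]
        cds = [(g, s) for g, s in cds if len(s) % 3 == 0]
        table = codons.count_codons(cds)
        rows = [{"codon": c, "count": table.counts[c],
                 "rscu": (round(v, 2) if v is not None else ""),
                 "family_pct": (round(p, 1) if p is not None else "")}
                for c, v, p in zip(codons.ALL_CODONS,
                                   (table.rscu[c] for c in codons.ALL_CODONS),
                                   (table.aa_fraction[c] for c in codons.ALL_CODONS))]
        write_tsv(rows, out / "codon_usage.tsv",
                  ["codon", "count", "rscu", "family_pct"])
        report["stages"]["codon_usage"] = {"total_codons": table.total_codons,
                                           "table": "codon_usage.tsv"}

    if "ssr" in stages:
        genome = plastome or read_plastome(require("genome", "ssr"))
        loci = repeats.find_ssrs(genome,
                                 thresholds=config.get("ssr_thresholds"))
        loci = repeats.classify_context(loci, feats, len(genome))
        rows = [{"motif": l.motif, "unit_len": l.unit_len, "copies": l.copies,
                 "start": l.start, "end": l.end, "length": l.length,
                 "kind": l.kind,
                 "context": l.context[0] if l.context else "",
                 "gene": (l.context[1] or "") if l.context else ""}
                for l in loci]
        write_tsv(rows, out / "ssrs.tsv",
                  ["motif", "unit_len", "copies", "start", "end", "length",
                   "kind", "context", "gene"])
        from .io import write_bed
        write_bed([(genome.id, l.start, min(l.end, len(genome)),
                    f"{l.motif}x{l.copies}") for l in loci], out / "ssrs.bed")
        report["stages"]["ssr"] = {"n_loci": len(loci), "table": "ssrs.tsv"}

    if "repeats" in stages:
        genome = plastome or read_plastome(require("genome", "repeats"))
        pairs = repeats.find_repeats(
            genome, min_len=int(config.get("min_repeat_len", 30)),
            max_mismatch=int(config.get("max_mismatch", 3)))
        rows = [{"kind": p.kind, "start1": p.pos1[0], "end1": p.pos1[1],
                 "start2": p.pos2[0], "end2": p.pos2[1], "length": p.length,
                 "mismatches": p.mismatches, "identity": round(p.identity, 1)}
                for p in pairs]
        write_tsv(rows, out / "repeats.tsv",
                  ["kind", "start1", "end1", "start2", "end2", "length",
                   "mismatches", "identity"])
        from .io import write_bed
        bed_rows = []
        for i, p in enumerate(pairs):
            bed_rows.append((genome.id, p.pos1[0], p.pos1[1], f"{p.kind}_{i}a"))
            bed_rows.append((genome.id, p.pos2[0], p.pos2[1], f"{p.kind}_{i}b"))
        write_bed(bed_rows, out / "repeats.bed")
        report["stages"]["repeats"] = {"n_pairs": len(pairs),
                                       "table": "repeats.tsv"}

    if "editing" in stages:
        genome = plastome or read_plastome(require("genome", "editing"))
        sam = require("sam", "editing")
        pileup = editing.build_pileup(
            sam, genome, min_base_qual=int(config.get("min_base_qual", 25)))
        sites = editing.call_editing_sites(
            pileup, feats, min_cov=int(config.get("min_cov", 10)),
            reference=genome)
        rows = [{"gene": s.gene or "", "position": s.position,
                 "strand": s.strand or "", "direction": s.direction,
                 "codon_from": s.codon_from or "", "codon_to": s.codon_to or "",
                 "codon_position": s.codon_position or "",
                 "aa_from": s.aa_from or "", "aa_to": s.aa_to or "",
                 "level": round(s.level, 1), "depth": s.depth}
                for s in sites]
        write_tsv(rows, out / "editing_sites.tsv",
                  ["gene", "position", "strand", "direction", "codon_from",
                   "codon_to", "codon_position", "aa_from", "aa_to", "level",
                   "depth"])
        counts, total = editing.gene_read_counts(sam, feats, len(genome))
        lengths = {f.gene: f.spliced_length(len(genome)) for f in feats}
        expr = editing.rpkm_quantify(counts, lengths, total) if total else []
        write_tsv([{"gene": r.gene, "unique_reads": r.unique_reads,
                    "gene_len": r.gene_len, "rpkm": round(r.rpkm, 2)}
                   for r in expr], out / "expression.tsv",
                  ["gene", "unique_reads", "gene_len", "rpkm"])
        report["stages"]["editing"] = {"n_sites": len(sites),
                                       "total_unique_reads": total,
                                       "tables": ["editing_sites.tsv",
                                                  "expression.tsv"]}

    if "trace" in stages:
        tree = parsimony.load_tree(require("tree", "trace"))
        matrix_path = require("matrix", "trace")
        import pandas as pd
        mdf = pd.read_csv(matrix_path, sep="\t", index_col=0)
        trace = {}
        for gene in mdf.columns:
            character = {t: int(v) for t, v in mdf[gene].items()}
            score = parsimony.fitch_score(tree, character)
            mprs = parsimony.enumerate_mprs(tree, character, name=gene)
            trace[gene] = {
                "fitch_score": score,
                "n_mprs": len(mprs),
                "reconstructions": [
                    {"label": r.label, "events": r.events,
                     "n_changes": r.n_changes} for r in mprs],
            }
        report["stages"]["trace"] = trace

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
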