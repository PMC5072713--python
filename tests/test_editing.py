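"""Pileup construction, editing-site calling, codon effects and RPKM."""

import pytest

import oracles
from plastokit import (EditingSite, GeneFeature, PileupColumn, PlastomeSeq,
                       annotate_codon_effect, build_pileup, call_editing_sites,
                       rpkm_quantify)
from plastokit._util import revcomp


def write_sam(path, ref_id, ref_len, rows):
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n")
        fh.write(f"@SQ\tSN:{ref_id}\tLN:{ref_len}\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_row(name, pos, seq, qual=None, flag=0, mapq=60, cigar=None, extra=()):
    cigar = cigar or f"{len(seq)}M"
    qual = qual or "I" * len(seq)
    return [name, flag, "ref", pos, mapq, cigar, "*", 0, 0, seq, qual, *extra]


class TestBuildPileup:
    def test_uniform_matches(self, tmp_path):
        ref = PlastomeSeq("ref", "ACGTACGTAC", circular=False)
        sam = tmp_path / "a.sam"
        write_sam(sam, "ref", 10, [read_row(f"r{i}", 3, "GTACG")
                                   for i in range(10)])
        pileup = build_pileup(sam, ref)
        col = next(c for c in pileup if c.position == 5)
        assert col.counts == {"A": 10} and col.depth == 10

    def test_quality_filter(self, tmp_path):
        ref = PlastomeSeq("ref", "ACGTACGTAC", circular=False)
        sam = tmp_path / "q.sam"
        rows = [read_row(f"hi{i}", 5, "ACG") for i in range(7)]
        rows += [read_row(f"lo{i}", 5, "ACG", qual="555") for i in range(3)]
        write_sam(sam, "ref", 10, rows)       # '5' is phred 20, below 25
        pileup = build_pileup(sam, ref)
        col = next(c for c in pileup if c.position == 5)
        assert col.depth == 7

    def test_multimappers_and_secondary_dropped(self, tmp_path):
        ref = PlastomeSeq("ref", "ACGTACGTAC", circular=False)
        sam = tmp_path / "m.sam"
        rows = [read_row("u", 1, "ACGT"),
                read_row("multi", 1, "ACGT", extra=("NH:i:3",)),
                read_row("sec", 1, "ACGT", flag=256),
                read_row("mapq0", 1, "ACGT", mapq=0)]
        write_sam(sam, "ref", 10, rows)
        pileup = build_pileup(sam, ref)
        assert all(c.depth == 1 for c in pileup)

    def test_unsupported_cigar_rejected(self, tmp_path):
        ref = PlastomeSeq("ref", "ACGTACGTAC", circular=False)
        sam = tmp_path / "p.sam"
        write_sam(sam, "ref", 10, [read_row("r", 1, "ACGT", cigar="2M2P2M")])
        with pytest.raises(ValueError, match="CIGAR"):
            build_pileup(sam, ref)

    def test_equals_naive_cigar_walker(self, tmp_path):
        seq = "ACGTACGTACGTACGTACGTACGTACGTAC"
        ref = PlastomeSeq("ref", seq, circular=True)
        rows = [
            read_row("plain", 1, seq[:12]),
            read_row("mismatch", 3, "TTTT"),
            read_row("softclip", 5, "GGGG" + seq[4:10], cigar="4S6M"),
            read_row("insertion", 7, seq[6:10] + "AA" + seq[10:14],
                     cigar="4M2I4M"),
            read_row("deletion", 2, seq[1:5] + seq[8:12], cigar="4M3D4M"),
            read_row("skip", 4, seq[3:7] + seq[17:21], cigar="4M10N4M"),
            read_row("hardclip", 9, seq[8:14], cigar="3H6M"),
            read_row("wrap", 28, seq[27:30] + seq[:5], cigar="8M"),
            read_row("lowq", 6, seq[5:11], qual="5I5I5I"),
        ]
        sam = tmp_path / "walker.sam"
        write_sam(sam, "ref", len(seq), rows)
        pileup = build_pileup(sam, ref)
        got = {c.position: dict(c.counts) for c in pileup}
        assert got == oracles.naive_pileup(sam, seq, circular=True)


class TestCallSites:
    def _column(self, pos, ref, counts):
        return PileupColumn(position=pos, ref_base=ref, counts=counts)

    def test_high_level_c_to_u(self):
        (site,) = call_editing_sites(
            [self._column(10, "C", {"T": 99, "C": 1})], [])
        assert site.direction == "C->U"
        assert site.level == pytest.approx(99.0)
        assert site.gene is None and site.codon_from is None

    def test_below_coverage_not_called(self):
        assert call_editing_sites(
            [self._column(10, "C", {"T": 9})], []) == []

    def test_reverse_direction_u_to_c(self):
        (site,) = call_editing_sites(
            [self._column(4, "T", {"C": 85, "T": 15})], [])
        assert site.direction == "U->C"
        assert site.level == pytest.approx(85.0)

    def test_minus_strand_gene_resolves_g_to_a(self):
        gene = GeneFeature(gene="m", type="CDS", strand="-", exons=[(1, 30)])
        (site,) = call_editing_sites(
            [self._column(12, "G", {"A": 40, "G": 60})], [gene])
        assert site.direction == "C->U" and site.strand == "-"
        assert site.level == pytest.approx(40.0)

    def test_min_alt_fraction_suppresses_singletons(self):
        assert call_editing_sites(
            [self._column(3, "C", {"C": 99, "T": 1})], []) == []

    def test_doubling_counts_leaves_level_unchanged(self):
        a = call_editing_sites([self._column(5, "C", {"T": 30, "C": 70})], [])
        b = call_editing_sites([self._column(5, "C", {"T": 60, "C": 140})], [])
        assert a[0].level == pytest.approx(b[0].level)


class TestCodonEffect:
    def test_first_position_his_to_tyr(self):
        genome = PlastomeSeq("g", "TTT" + "ATGCACAACTAA" + "GG", circular=False)
        gene = GeneFeature(gene="x", type="CDS", strand="+", exons=[(4, 15)])
        site = EditingSite(position=7, gene="x", strand="+", direction="C->U",
                           level=15.0, depth=100, edited_reads=15,
                           reference_reads=85)
        annotate_codon_effect(site, gene, genome)
        assert (site.codon_from, site.codon_to) == ("CAC", "UAC")
        assert (site.aa_from, site.aa_to) == ("H", "Y")
        assert site.codon_position == 1 and site.synonymous is False

    def test_third_position_synonymous(self):
        genome = PlastomeSeq("g", "TTT" + "ATGCACAACTAA" + "GG", circular=False)
        gene = GeneFeature(gene="x", type="CDS", strand="+", exons=[(4, 15)])
        site = EditingSite(position=12, gene="x", strand="+", direction="C->U",
                           level=11.0, depth=90, edited_reads=10,
                           reference_reads=80)
        annotate_codon_effect(site, gene, genome)
        assert (site.codon_from, site.codon_to) == ("AAC", "AAU")
        assert (site.aa_from, site.aa_to) == ("N", "N")
        assert site.codon_position == 3 and site.synonymous is True

    def test_minus_strand_middle_base(self):
        # 30 bp toy gene on the minus strand: CDS = ATG CCA ... TAA; the C at
        # CDS offset 4 (codon 2, position 2) sits at genomic position
        # end - offset = 30 - 4 = 26 as a G on the plus strand
        cds = "ATGCCAGATGAAGTTCATAAGTTTGGGTAA"
        genome = PlastomeSeq("g", revcomp(cds), circular=False)
        gene = GeneFeature(gene="m", type="CDS", strand="-", exons=[(1, 30)])
        assert genome.sequence[26 - 1] == "G"
        site = EditingSite(position=26, gene="m", strand="-", direction="C->U",
                           level=50.0, depth=20, edited_reads=10,
                           reference_reads=10)
        annotate_codon_effect(site, gene, genome)
        assert site.codon_position == 2
        assert (site.codon_from, site.codon_to) == ("CCA", "CUA")
        assert (site.aa_from, site.aa_to) == ("P", "L")

    def test_intronic_site_rejected(self):
        genome = PlastomeSeq("g", "ATGCAC" + "GTTTTTAG" + "AACTAA",
                             circular=False)
        gene = GeneFeature(gene="s", type="CDS", strand="+",
                           exons=[(1, 6), (15, 20)])
        site = EditingSite(position=10, gene="s", strand="+", direction="C->U",
                           level=50.0, depth=20, edited_reads=10,
                           reference_reads=10)
        with pytest.raises(ValueError, match="intron"):
            annotate_codon_effect(site, gene, genome)


class TestRpkm:
    def test_reference_values(self):
        (rec,) = rpkm_quantify({"g": 10}, {"g": 1000}, 1_000_000)
        assert rec.rpkm == pytest.approx(10.0)
        (rec,) = rpkm_quantify({"g": 0}, {"g": 500}, 1_000_000)
        assert rec.rpkm == 0.0
        (rec,) = rpkm_quantify({"g": 500}, {"g": 250}, 113_224)
        assert round(rec.rpkm, 2) == 17_664.10

    def test_scaling_invariance(self):
        (a,) = rpkm_quantify({"g": 10}, {"g": 1000}, 100_000)
        (b,) = rpkm_quantify({"g": 20}, {"g": 1000}, 200_000)
        assert a.rpkm == pytest.approx(b.rpkm)

    def test_zero_length_gene_rejected(self):
        with pytest.raises(ValueError):
            rpkm_quantify({"g": 1}, {"g": 0}, 100)
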