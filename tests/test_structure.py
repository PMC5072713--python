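"""Quadripartite architecture detection, region GC and composition accounting."""

import numpy as np
import pytest

import oracles
from plastokit import (CompositionSummary, GeneFeature, PlastomeSeq,
                       composition_summary, detect_inverted_repeats,
                       gc_percent, junction_report, region_gc)
from plastokit._util import revcomp
from tests_helpers import planted_ir_genome


def test_planted_ir_recovered_exactly(rng):
    genome, coords = planted_ir_genome(rng, lsc=5000, ir=1200, ssc=2000)
    part = detect_inverted_repeats(genome, min_ir_len=1000)
    assert part.ir_length == 1200
    assert part.lsc == (1, 5000)
    assert part.irb == (5001, 6200)
    assert part.ssc == (6201, 8200)
    assert part.ira == (8201, 9400)


@pytest.mark.parametrize("offset", [1, 137, 4999, 6200, 9000])
def test_rotation_invariance(rng, offset):
    genome, _ = planted_ir_genome(rng, lsc=5000, ir=1200, ssc=2000)
    part = detect_inverted_repeats(genome, min_ir_len=1000)
    rotated = detect_inverted_repeats(genome.rotated(offset), min_ir_len=1000)
    assert rotated.lengths() == part.lengths()
    assert rotated.ir_length == part.ir_length


def test_revcomp_invariance(rng):
    genome, _ = planted_ir_genome(rng, lsc=4000, ir=1100, ssc=1500)
    flipped = PlastomeSeq("rc", revcomp(genome.sequence), circular=True)
    a = detect_inverted_repeats(genome, min_ir_len=1000)
    b = detect_inverted_repeats(flipped, min_ir_len=1000)
    assert a.lengths() == b.lengths()


def test_partition_covers_genome_once(rng):
    genome, _ = planted_ir_genome(rng, lsc=3000, ir=1050, ssc=900)
    part = detect_inverted_repeats(genome, min_ir_len=1000)
    seen = np.zeros(len(genome), dtype=int)
    for a, b in part.regions().values():
        for pos in range(a, b + 1) if a <= b else \
                list(range(a, len(genome) + 1)) + list(range(1, b + 1)):
            seen[pos - 1] += 1
    assert (seen == 1).all()


def test_no_ir_returns_none(rng):
    from conftest import random_dna
    seq = random_dna(rng, 3000)
    genome = PlastomeSeq("flat", seq, circular=True)
    assert detect_inverted_repeats(genome, min_ir_len=1000) is None


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_agrees_with_quadratic_oracle(seed):
    rng = np.random.default_rng(seed)
    from conftest import random_dna
    core = random_dna(rng, 60 + int(rng.integers(0, 60)))
    seq = (random_dna(rng, 300) + core + random_dna(rng, 150)
           + oracles.revcomp(core) + random_dna(rng, 100))
    genome = PlastomeSeq("toy", seq, circular=False)
    expected = oracles.longest_disjoint_inverted_pair(seq)
    part = detect_inverted_repeats(genome, min_ir_len=30, k=15)
    assert part is not None and part.ir_length == expected


def test_gc_percent_basics():
    assert gc_percent("ATAT") == 0.0
    assert gc_percent("GGCC") == 100.0
    assert gc_percent("NNNN") is None
    # N excluded from numerator and denominator
    assert gc_percent("GCNN") == 100.0
    assert gc_percent("GCAT") == 50.0


def test_region_gc_reports_all_regions(rng):
    genome, _ = planted_ir_genome(rng, lsc=3000, ir=1050, ssc=900)
    part = detect_inverted_repeats(genome, min_ir_len=1000)
    gc = region_gc(genome, part)
    assert set(gc) == {"LSC", "IRb", "SSC", "IRa", "genome"}
    assert gc["IRb"] == pytest.approx(gc["IRa"], abs=1e-9)
    assert all(0 <= v <= 100 for v in gc.values())


class TestJunctionReport:
    def _partition(self, rng):
        genome, _ = planted_ir_genome(rng, lsc=5000, ir=1200, ssc=2000)
        return detect_inverted_repeats(genome, min_ir_len=1000)

    def test_spanning_gene_reported_with_overlaps(self, rng):
        part = self._partition(rng)
        gene = GeneFeature(gene="g1", type="CDS", strand="+", exons=[(6100, 6400)])
        rep = junction_report(part, [gene])
        irb_ssc = next(j for j in rep if j["junction"] == "IRb/SSC")
        (span,) = irb_ssc["spanning"]
        assert span["gene"] == "g1"
        assert span["overlap_upstream"] == 101    # 6100..6200 inside IRb
        assert span["overlap_downstream"] == 200  # 6201..6400 inside SSC

    def test_two_ycf1_like_copies_at_both_ir_ssc_junctions(self, rng):
        part = self._partition(rng)
        big = GeneFeature(gene="ycf1", type="CDS", strand="+", exons=[(6150, 6600)])
        small = GeneFeature(gene="ycf1_2", type="pseudogene", strand="-",
                            exons=[(8100, 8350)])
        rep = junction_report(part, [big, small])
        by_name = {j["junction"]: j for j in rep}
        assert [s["gene"] for s in by_name["IRb/SSC"]["spanning"]] == ["ycf1"]
        assert [s["gene"] for s in by_name["SSC/IRa"]["spanning"]] == ["ycf1_2"]

    def test_empty_features_give_empty_contexts(self, rng):
        part = self._partition(rng)
        for j in junction_report(part, []):
            assert j["spanning"] == []
            assert j["nearest_upstream"] is None
            assert j["nearest_downstream"] is None


class TestComposition:
    def test_no_features_all_intergenic(self):
        comp = composition_summary([], 1000)
        assert comp.bp["intergenic"] == 1000
        assert comp.fraction("intergenic") == 1.0

    def test_overlapping_cds_counted_once(self):
        # two 100 bp CDS overlapping by 40 bp -> 160 bp, per-base oracle
        f1 = GeneFeature(gene="a", type="CDS", strand="+", exons=[(1, 100)])
        f2 = GeneFeature(gene="b", type="CDS", strand="+", exons=[(61, 160)])
        comp = composition_summary([f1, f2], 500)
        marked = set(range(1, 101)) | set(range(61, 161))
        assert comp.bp["CDS"] == len(marked) == 160

    def test_precedence_cds_over_rna_over_intron(self):
        cds = GeneFeature(gene="c", type="CDS", strand="+", exons=[(1, 90)])
        trna = GeneFeature(gene="t", type="tRNA", strand="+", exons=[(81, 120)])
        two_exon = GeneFeature(gene="x", type="CDS", strand="+",
                               exons=[(200, 229), (261, 290)])
        comp = composition_summary([cds, trna, two_exon], 400)
        assert comp.bp["CDS"] == 90 + 60
        assert comp.bp["tRNA"] == 30          # 81..90 yielded to CDS
        assert comp.bp["intron"] == 31        # 230..260
        assert sum(comp.bp.values()) == 400

    def test_coding_total_identity(self):
        comp = CompositionSummary(bp={"CDS": 57159, "tRNA": 2766, "rRNA": 9044,
                                      "intron": 16811, "pseudogene": 6453,
                                      "intergenic": 47492}, genome_len=139725)
        assert comp.coding_total == 68969
        assert round(100 * comp.fraction("CDS"), 1) == 40.9
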