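"""Microsatellite and dispersed-repeat scanners against brute-force oracles."""

from collections import Counter

import numpy as np
import pytest

import oracles
from plastokit import (PlastomeSeq, canonical_motif, find_repeats, find_ssrs,
                       classify_context, GeneFeature)
from plastokit.repeats import DEFAULT_SSR_THRESHOLDS
from plastokit._util import revcomp
from tests_helpers import random_dna


def linear(seq: str) -> PlastomeSeq:
    return PlastomeSeq("t", seq, circular=False)


class TestCanonicalMotif:
    def test_complement_classes(self):
        assert canonical_motif("T") == "A"
        assert canonical_motif("G") == "C"
        assert canonical_motif("TA") == canonical_motif("AT") == "AT"
        assert canonical_motif("TTC") == "AAG"

    def test_rotation_classes(self):
        assert canonical_motif("TCA") == canonical_motif("CAT") == \
            canonical_motif("ATC")


class TestFindSsrs:
    def test_mono_run_at_threshold(self):
        loci = find_ssrs(linear("CC" + "A" * 7 + "GG"))
        assert len(loci) == 1
        (l,) = loci
        assert (l.motif, l.unit_len, l.copies, l.start, l.end) == ("A", 1, 7, 3, 9)

    def test_below_threshold_not_reported(self):
        assert find_ssrs(linear("CC" + "A" * 6 + "GG")) == []

    def test_di_run_without_spurious_mono_calls(self):
        seq = "CCG" + "AT" * 4 + "GCC"
        loci = find_ssrs(linear(seq))
        assert len(loci) == 1
        assert loci[0].unit_len == 2 and loci[0].copies == 4
        # brute-force enumeration agrees: a single qualifying run
        assert oracles.brute_ssrs(seq, DEFAULT_SSR_THRESHOLDS) == {(4, 2, 4)}

    def test_run_not_reported_for_multiple_of_its_period(self):
        loci = find_ssrs(linear("G" + "A" * 14 + "C"))
        assert len(loci) == 1 and loci[0].unit_len == 1

    def test_compound_locus_within_gap(self):
        seq = "G" + "A" * 8 + random_gap(50) + "CT" * 5 + "G"
        loci = find_ssrs(linear(seq))
        assert len(loci) == 1
        (l,) = loci
        assert l.kind == "compound" and len(l.members) == 2
        assert l.spacers == [50]

    def test_no_compound_beyond_gap(self):
        seq = "G" + "A" * 8 + random_gap(101) + "CT" * 5 + "G"
        loci = find_ssrs(linear(seq))
        assert [l.kind for l in loci] == ["simple", "simple"]

    def test_circular_run_across_origin(self):
        seq = "AAA" + random_gap(60) + "AAAA"     # A7 wraps the origin
        loci = find_ssrs(PlastomeSeq("c", seq, circular=True))
        assert len(loci) == 1
        (l,) = loci
        assert l.copies == 7 and l.start == len(seq) - 3
        # the same sequence treated linearly has no qualifying run
        assert find_ssrs(linear(seq)) == []

    def test_revcomp_invariance_of_class_counts(self, rng):
        seq = (random_dna(rng, 300) + "A" * 9 + random_dna(rng, 90)
               + "TA" * 5 + random_dna(rng, 120) + "GGC" * 4
               + random_dna(rng, 200))
        a = find_ssrs(linear(seq))
        b = find_ssrs(linear(revcomp(seq)))

        def count(loci):
            # compound members read in opposite order on the other strand
            return Counter(
                tuple(sorted((m.motif, m.unit_len, m.copies)
                             for m in (l.members or [l])))
                for l in loci)

        assert count(a) == count(b)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_brute_force_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        # AT-rich background makes qualifying runs likely
        seq = "".join(np.array(list("AATTACGT"))[rng.integers(0, 8, size=2000)])
        got = {(m.start, m.unit_len, m.copies)
               for l in find_ssrs(linear(seq)) for m in (l.members or [l])}
        assert got == oracles.brute_ssrs(seq, DEFAULT_SSR_THRESHOLDS)

    def test_no_reported_run_is_extendable(self, rng):
        seq = "".join(np.array(list("AATTACGT"))[rng.integers(0, 8, size=1500)])
        for locus in find_ssrs(linear(seq)):
            for m in (locus.members or [locus]):
                p, s, e = m.unit_len, m.start - 1, m.end - 1
                motif = seq[s:s + p]
                assert seq[e + 1:e + 1 + p] != motif
                assert seq[max(0, s - p):s] != motif


def random_gap(n: int) -> str:
    # fixed low-complexity-free spacer of the requested length
    pattern = "GACTGCTAGCATCGGATCCTAGCTAAGCTTGGCAATGCCGGATTACAGGC"
    out = (pattern * (n // len(pattern) + 1))[:n]
    return out


class TestFindRepeats:
    def test_planted_forward_copy(self, rng):
        core = random_dna(rng, 35)
        seq = random_dna(rng, 400) + core + random_dna(rng, 300) + core \
            + random_dna(rng, 200)
        pairs = [p for p in find_repeats(linear(seq), min_len=30)
                 if p.kind == "forward"]
        # the exact planted copy sits inside a maximal reported window and is
        # mismatch-free over the planted columns
        covering = [p for p in pairs
                    if p.pos1[0] <= 401 and p.pos1[1] >= 435
                    and p.pos2[0] <= 736 and p.pos2[1] >= 770]
        assert covering
        assert all(p.mismatches <= 3 for p in covering)
        off = 401 - covering[0].pos1[0]
        s1, s2 = covering[0].pos1[0] - 1, covering[0].pos2[0] - 1
        assert seq[s1 + off:s1 + off + 35] == seq[s2 + off:s2 + off + 35] == core

    def test_planted_palindromic_copy_with_two_substitutions(self, rng):
        core = random_dna(rng, 35)
        mate = list(revcomp(core))
        mate[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mate[5]]
        mate[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mate[20]]
        seq = random_dna(rng, 350) + core + random_dna(rng, 250) \
            + "".join(mate) + random_dna(rng, 150)
        pairs = [p for p in find_repeats(linear(seq), min_len=30)
                 if p.kind == "palindromic"]
        assert pairs, "planted palindromic pair not found"
        best = max(pairs, key=lambda p: p.length)
        assert best.mismatches <= 3 and best.length >= 35

    def test_too_divergent_copy_not_reported(self, rng):
        core = random_dna(rng, 30)
        mate = list(core)
        for i in (2, 9, 17, 25):
            mate[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mate[i]]
        seq = random_dna(rng, 300) + core + random_dna(rng, 200) \
            + "".join(mate) + random_dna(rng, 100)
        for p in find_repeats(linear(seq), min_len=30, max_mismatch=3):
            # no reported window corresponds to the 4-substitution copy
            assert p.mismatches <= 3

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        core1, core2 = random_dna(rng, 40), random_dna(rng, 34)
        mate2 = list(revcomp(core2))
        mate2[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mate2[10]]
        seq = (random_dna(rng, 150) + core1 + random_dna(rng, 90) + core1
               + random_dna(rng, 120) + core2 + random_dna(rng, 80)
               + "".join(mate2) + random_dna(rng, 60))
        got = {(p.kind, p.pos1, p.pos2, p.length, p.mismatches)
               for p in find_repeats(linear(seq), min_len=30, filter_ssr=False)}
        assert got == oracles.brute_repeat_pairs(seq, 30, 3)

    def test_no_reported_pair_is_extendable(self, rng):
        core = random_dna(rng, 36)
        seq = random_dna(rng, 200) + core + random_dna(rng, 150) + core \
            + random_dna(rng, 100)
        for p in find_repeats(linear(seq), min_len=30, filter_ssr=False):
            if p.kind != "forward":
                continue
            (a0, a1), (b0, b1) = p.pos1, p.pos2
            # left extension
            if a0 > 1 and b0 > 1:
                mm = sum(x != y for x, y in zip(seq[a0 - 2:a1], seq[b0 - 2:b1]))
                assert mm > 3
            if a1 < len(seq) and b1 < len(seq):
                mm = sum(x != y for x, y in zip(seq[a0 - 1:a1 + 1],
                                                seq[b0 - 1:b1 + 1]))
                assert mm > 3

    def test_min_len_guard(self):
        with pytest.raises(ValueError):
            find_repeats(linear("ACGT" * 10), min_len=4)


class TestContext:
    def _features(self):
        return [
            GeneFeature(gene="cds1", type="CDS", strand="+", exons=[(100, 400)]),
            GeneFeature(gene="split", type="CDS", strand="+",
                        exons=[(600, 700), (801, 900)]),
        ]

    def test_coding_intron_and_intergenic(self):
        plast = linear("G" + "A" * 7 + "C")
        (locus,) = find_ssrs(plast)
        feats = self._features()

        locus.start, locus.end = 200, 206
        assert classify_context([locus], feats)[0].context == ("coding", "cds1")

        locus.start, locus.end = 730, 736
        assert classify_context([locus], feats)[0].context == ("intron", "split")

        locus.start, locus.end = 450, 456
        assert classify_context([locus], feats)[0].context == ("intergenic", None)
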