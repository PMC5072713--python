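"""Synthetic-data generator: determinism, planted-truth recovery, feasibility."""

import numpy as np
import pytest

from plastokit import (canonical_motif, classify_gene, detect_inverted_repeats,
                       find_repeats, find_ssrs, build_pileup,
                       call_editing_sites)
from plastokit.synth import (EditSpec, GeneSpec, SynthesisConfig,
                             default_config, generate_plastome, simulate_reads)


def test_same_seed_is_byte_identical(tmp_path):
    cfg = default_config(seed=7)
    g1, f1, t1 = generate_plastome(cfg)
    g2, f2, t2 = generate_plastome(default_config(seed=7))
    assert g1.sequence == g2.sequence
    assert [x.exons for x in f1] == [x.exons for x in f2]
    assert t1.as_dict() == t2.as_dict()
    r1 = simulate_reads(g1, f1, t1, cfg, tmp_path / "a.sam")
    r2 = simulate_reads(g2, f2, t2, cfg, tmp_path / "b.sam")
    assert (tmp_path / "a.sam").read_bytes() == (tmp_path / "b.sam").read_bytes()
    assert r1 == r2


def test_different_seed_differs():
    g1, _, _ = generate_plastome(default_config(seed=1))
    g2, _, _ = generate_plastome(default_config(seed=2))
    assert g1.sequence != g2.sequence


def test_planted_ir_length_recovered_exactly():
    cfg = SynthesisConfig(seed=3, lsc_len=18_000, ir_len=12_000, ssc_len=6_000,
                          gc={"lsc": 0.36, "irb": 0.43, "ssc": 0.32})
    genome, _, truth = generate_plastome(cfg)
    part = detect_inverted_repeats(genome, min_ir_len=5_000)
    assert part.ir_length == 12_000
    assert part.lengths() == {"LSC": 18_000, "IRb": 12_000,
                              "SSC": 6_000, "IRa": 12_000}


def test_infeasible_config_rejected():
    cfg = SynthesisConfig(seed=1, lsc_len=1_000, ir_len=1_000, ssc_len=1_000,
                          gc={"lsc": 0.4, "irb": 0.4, "ssc": 0.4},
                          genes=[GeneSpec("big", 900, "+", "lsc")])
    with pytest.raises(ValueError, match="too small"):
        generate_plastome(cfg)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_planted_ssrs_recovered_with_full_precision_and_recall(seed):
    genome, _, truth = generate_plastome(default_config(seed))
    found = {(l.start, l.end, l.motif)
             for loc in find_ssrs(genome) for l in (loc.members or [loc])}
    planted = {(t["start"], t["end"], canonical_motif(t["motif"]))
               for t in truth.ssrs}
    assert found == planted


def test_planted_repeats_recovered(synth_bundle):
    genome, truth = synth_bundle.genome, synth_bundle.truth
    pairs = find_repeats(genome)
    ir = truth.region_lengths
    ir_span = (ir["lsc"] + 1, ir["lsc"] + ir["irb"])
    ira_span = (ir["lsc"] + ir["irb"] + ir["ssc"] + 1, len(genome))

    def covers(pair, t):
        return (pair.kind == t["kind"]
                and pair.pos1[0] <= t["pos1"][0] and pair.pos1[1] >= t["pos1"][1]
                and pair.pos2[0] <= t["pos2"][0] and pair.pos2[1] >= t["pos2"][1])

    def overlaps(pair, t):
        # maximal windows may trade flanking extension left/right around the
        # planted columns; explained = same kind, both intervals overlap
        def ov(a, b):
            return a[0] <= b[1] and b[0] <= a[1]
        return pair.kind == t["kind"] and ov(pair.pos1, t["pos1"]) \
            and ov(pair.pos2, t["pos2"])

    # recall: every planted pair lies inside a reported maximal window
    for t in truth.repeats:
        assert any(covers(p, t) for p in pairs), t
    # precision: every reported pair is explained by a planted repeat or by
    # the inverted-repeat pair itself
    def is_ir_pair(p):
        return (p.kind == "palindromic"
                and abs(p.pos1[0] - ir_span[0]) <= 5
                and abs(p.pos2[1] - ira_span[1]) <= 5)

    for p in pairs:
        assert any(overlaps(p, t) for t in truth.repeats) or is_ir_pair(p), p


def test_planted_lesions_classified_as_designed(synth_bundle):
    expected_criteria = {"stop": "a", "frameshift": "c",
                         "truncate20": "d", "no_start": "b"}
    for g in synth_bundle.truth.genes:
        status = classify_gene(g["observed_cds"], g["reference_cds"],
                               gene=g["name"])
        if g["lesion"] == "none":
            assert status.status == "intact"
        else:
            assert status.status == "pseudogene"
            assert expected_criteria[g["lesion"]] in status.criteria


def test_full_level_site_edits_every_covering_read(tmp_path):
    cfg = SynthesisConfig(
        seed=5, lsc_len=4_000, ir_len=1_200, ssc_len=1_000,
        gc={"lsc": 0.36, "irb": 0.43, "ssc": 0.32},
        genes=[GeneSpec("only", 600, "+", "lsc")],
        editing=[EditSpec("only", 120, "C->U", 100.0)],
        expression={"only": 10.0}, n_reads=400)
    genome, feats, truth = generate_plastome(cfg)
    rt = simulate_reads(genome, feats, truth, cfg, tmp_path / "r.sam")
    (site,) = truth.editing
    per = rt["per_site"][site["position"]]
    assert per["total"] > 0 and per["edited"] == per["total"]
    pileup = build_pileup(tmp_path / "r.sam", genome)
    (called,) = call_editing_sites(pileup, feats, reference=genome)
    assert called.position == site["position"]
    assert called.level == pytest.approx(100.0)


def test_unplanted_position_not_called(synth_bundle):
    pileup = build_pileup(synth_bundle.sam, synth_bundle.genome)
    called = call_editing_sites(pileup, synth_bundle.features,
                                reference=synth_bundle.genome)
    planted = {e["position"] for e in synth_bundle.truth.editing}
    assert {s.position for s in called} == planted
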