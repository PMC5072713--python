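# plastokit

Analysis toolkit for chloroplast (plastid) genomes, built around the study
system of the terrestrial carnivorous bladderwort *Utricularia reniformis*
and its Lentibulariaceae relatives. It is aimed at plant organellar
genomicists who have an assembled, annotated plastome (plus, optionally,
aligned RNA-seq reads and a species tree) and want the standard downstream
analyses as tested, scriptable functions rather than a chain of web tools.

## What it computes

**Quadripartite structure.** Land-plant plastomes are circular molecules
organised as a large single-copy region (LSC), a small single-copy region
(SSC) and two identical inverted repeats (IRa/IRb).
`detect_inverted_repeats` finds the maximal pair of disjoint,
reverse-complementary intervals by seed-and-extend (exact matches, k = 21)
and derives the partition; the result is invariant under rotation of the
circular sequence. Companion functions report per-region GC, the gene
context of the four region junctions, and a per-base composition summary
(CDS / tRNA / rRNA / intron / pseudogene / intergenic, with precedence so
coding categories are never diluted).

**Codon usage.** `count_codons` tallies the 64 codons over spliced,
strand-corrected CDSs (start and stop included) and computes RSCU —
relative synonymous codon usage,

&nbsp;&nbsp;&nbsp;&nbsp;RSCU(c) = n_c / mean(n over c's synonymous family),

with the three stops treated as one family. `trna_decoding_coverage`
derives the set of codons an annotated tRNA set can read by anticodon
reverse-complement pairing, with the lysidine exception (plastid trnI-CAU
reads AUA; trnM/trnfM-CAU read AUG).

**Pseudogene classification.** `classify_gene` aligns an observed locus to
an intact reference CDS (global, affine gaps, free end gaps) and applies
four independent criteria: (a) in-frame stop, (b) start codon outside
{AUG, GUG, AUC} or missing terminal stop, (c) frameshift (net internal
indels not a multiple of 3, ignoring the final 5% of the CDS), (d) aligned
reference coverage below 80%. Statuses feed a binary character matrix
(1 = functional; pseudogenes and frameshifts count as absences).

**Repeats.** `find_ssrs` scans for perfect microsatellite runs at the
conventional plastome thresholds (mono ≥ 7, di/tri ≥ 4, tetra–hexa ≥ 3
copies), merges qualifying runs separated by ≤ 100 bp into compound loci,
and reports motifs as canonical classes under rotation and reverse
complement. `find_repeats` reports maximal forward and palindromic repeat
pairs ≥ 30 bp within a Hamming distance of 3 (≥ 90% identity).

**RNA editing and expression.** `build_pileup` makes quality-filtered base
counts (phred ≥ 25) from primary, uniquely mapped SAM records;
`call_editing_sites` calls C→U / U→C sites at ≥ 10× coverage, resolves the
substitution against the host gene's strand, computes the editing level as
the percentage of edited reads U/(U+C), and annotates the codon and
amino-acid effect. `rpkm_quantify` computes
RPKM = reads × 10⁹ / (gene length × total unique mapped reads).

**Gene-history parsimony.** `fitch_score` and `enumerate_mprs` trace binary
gene presence/absence on a rooted species tree: the Fitch minimum number of
state changes, every most-parsimonious reconstruction (gain/loss events per
branch), and the ACCTRAN (changes rootward, favouring reversals) and
DELTRAN (changes tipward, favouring parallelisms) labels. Packaged data
cover the eleven-gene plastid *ndh* complex — NAD(P)H dehydrogenase
subunits involved in cyclic electron flow — across eight Lamiales taxa.

**Synthetic data.** `plastokit.synth` generates seeded plastomes with
planted IRs, SSRs, repeats, gene lesions and editing sites plus pre-aligned
RNA-seq reads, with every planted coordinate recorded in a truth set — so
each stage is testable end-to-end without downloads.

## Worked example

```python
from plastokit import fitch_score, enumerate_mprs, datasets

tree = datasets.lentibulariaceae_tree()
matrix = datasets.ndh_character_matrix()
for r in enumerate_mprs(tree, matrix.column("ndhB"), name="ndhB"):
    print(r.label, r.events)
```

prints

```
ACCTRAN [('N3', 'loss'), ('N1', 'gain')]
DELTRAN [('Genlisea_margaretae', 'loss'), ('Utricularia_reniformis', 'loss')]
```

— the two equally parsimonious histories of *ndhB* (two changes each):
either a single loss on the *Genlisea*–*Utricularia* stem (N3) followed by
a regain on the aquatic stem (N1), or independent losses in *Genlisea* and
*U. reniformis*. Similarly, the packaged codon table gives

```python
table = datasets.ureniformis_codon_counts()
table.total_codons        # 22601
round(table.rscu["UUA"], 2)   # 1.82 — the preferred leucine codon
```

and the annotated tRNA set decodes 29 of the 64 codons; wobble pairing
covers the rest. The `examples/` directory holds one short script per
capability (structure, codon usage, pseudogenes, repeats, editing/RPKM,
gene history); each prints the numbers it computes and a line on what they
mean. A thin CLI mirrors the library: `plastokit structure|codon-usage|
classify|ssr|repeats|edit-call|rpkm|trace|synth|run`.

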