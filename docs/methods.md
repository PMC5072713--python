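# Methods

This note documents the models, thresholds and numerical choices behind
plastokit, and what the synthetic test bed does and does not establish.

## Coordinates and sequence model

All genomic intervals are 1-based and inclusive on the plus strand
(GenBank convention); an interval whose start exceeds its end wraps the
origin of a circular molecule. BED output converts to 0-based half-open at
the writer boundary only. Features store exons in 5'→3' gene orientation;
splicing concatenates exons and reverse-complements minus-strand genes, so
every CDS-level computation (codon counting, editing-site codon effects)
operates on the coding strand.

## Inverted-repeat detection

The quadripartite partition is defined by the maximal-length pair of
disjoint intervals whose sequences are exact reverse complements
(mismatches = 0 by default). Detection is seed-and-extend: k-mers (k = 21,
reduced automatically for small minimum lengths) of the genome are indexed
and matched against the reverse complement, anchors are extended to
maximal matches with modular arithmetic on circular inputs, and the best
disjoint pair wins. LSC is the larger inter-IR gap, SSC the smaller; ties
among equally long pairs are broken by the IRb start after rotating the
origin to the LSC start, making the result deterministic and
rotation-invariant. A genome with no inverted repeat of at least
`min_ir_len` (default 10,000 bp) returns `None` — a recognisable "no-IR"
outcome rather than an error. A quadratic dynamic-programming oracle
validates the detector on sequences of a few hundred bp in the tests.

Region GC excludes N bases from numerator and denominator; an all-N region
reports as undefined. The composition summary assigns every genome
position to exactly one category with precedence
CDS > tRNA > rRNA > intron > pseudogene > intergenic — chosen so coding
categories are never diluted by overlapping annotations; introns are
derived from the gaps between a feature's exons.

## Codon usage

Counting uses the standard genetic code (plastid-specific behaviour is
limited to start-codon permissiveness, which is an annotation matter, not
a counting one). Start and stop codons are included; the three stops form
their own RSCU family, so a stop codon's RSCU is its count over the mean
stop count. Families with zero total have undefined RSCU (reported as
missing, never 0). Reporting rounds RSCU to 2 decimals and within-family
percentages to 1 decimal; stop shares are integer-rounded. tRNA decoding
is anticodon reverse complement with the lysidine exception: a
CAU-anticodon tRNA named trnI reads AUA (C34 is lysidine-modified), while
trnM/trnfM-CAU read AUG; duplicated genes count once.

## Pseudogene criteria

A locus is compared to its intact reference CDS by global alignment with
affine gaps (match +1, mismatch −1, open −5, extend −1) and free terminal
gaps. Terminal gaps are interpreted as missing coverage — they feed
criterion (d), aligned reference coverage < 80%, measured on nucleotides —
while internal gaps feed criterion (c): the net indel balance over
alignment columns within the first 95% of the reference must be a multiple
of 3, else the locus is frameshifted. The 5% tail exclusion keeps genuine
3' length polymorphism from flagging a frameshift; a compensated +1/−1
indel pair inside the window restores frame and deliberately does not
trigger. Criterion (a) scans reading frame 0 of the observed sequence for
a stop before the final codon; criterion (b) accepts AUG, GUG and AUC as
starts (the alternative starts observed in plastomes) and requires a
terminal stop. The criteria are independent: a frameshift typically also
creates a downstream in-frame stop, and both flags are then reported. The
character matrix codes 1 only for fully intact loci — pseudogenes and
frameshifts are absences for tracing purposes.

## Repeat scanning

SSRs are maximal perfect tandem runs (no internal mismatches), reported
when they reach the per-unit-length copy thresholds mono 7, di 4, tri 4,
tetra 3, penta 3, hexa 3; lengths count whole units only. A run is
attributed to its smallest period (an AT run is never additionally an
ATAT run), and motifs are canonicalised to the lexicographically smallest
rotation of the motif or its reverse complement, which makes strand- and
phase-independent motif classes well-defined. Qualifying runs separated by
at most 100 interrupting bases merge into one compound locus that records
its members and spacers. Circular genomes are scanned across the origin on
a doubled sequence with wrap-aware deduplication; compound merging across
the origin is not attempted.

Dispersed repeats are maximal windows under a Hamming budget: a pair of
equal-length intervals (forward, or palindromic via the reverse
complement) with at most 3 mismatches (so ≥ 90% identity at the 30 bp
minimum) that cannot be extended on either side without exceeding the
budget. Detection seeds on exact q-grams (q chosen by pigeonhole so every
qualifying window must contain a seed), clusters seeds per diagonal, scans
each cluster's mismatch profile once, and enumerates windows bounded by
real mismatches or the sequence ends. Because windows are maximal, a
planted exact copy is reported inside a window extended through up to 3
chance mismatches of flanking sequence, and several overlapping maximal
windows can trade left against right extension — the brute-force
per-diagonal oracle in the tests reproduces exactly this set. Pairs lying
entirely inside one SSR locus are filtered (tandem-internal matches), as
are self-overlapping pairs; no E-value model is applied, only
length/identity. The dispersed-repeat scan treats the molecule at its
deposited origin (linear); the SSR scan is fully circular.

## RNA editing and expression

Only primary, uniquely mapped alignments contribute (NH > 1 or mapping
quality 0 discards a record, with a counter in the log). The pileup drops
bases below phred 25; deletions and reference skips contribute no base,
insertions are ignored. On circular references, alignments running past
the end wrap; on linear ones they raise. A site is called when coverage
reaches 10× and the alternate fraction 0.05 — the latter is this package's
choice to suppress sequencing-error singletons at 10–100× depth, since
coverage and quality thresholds alone leave single-read artefacts. The
substitution is resolved against the host gene's strand (genomic G→A
inside a minus-strand CDS is C→U), and the editing level is the percentage
of edited reads among reads carrying either allele, U/(U+C) — this reading
is recorded in output metadata. Codon effects use spliced CDS coordinates
and the standard code. RPKM is reads × 10⁹ / (length × total unique
mapped); reads are assigned to genes by the midpoint of their aligned
span.

## Parsimony tracing

Scoring is unit-cost Sankoff (equal to the Fitch minimum, and valid on
polytomies). MPR enumeration backtracks through the dynamic program and
returns every internal-state assignment achieving the minimum. When both
root states are equally parsimonious, the root is fixed to the outgroup
leaf's state — the first leaf of the newick string — reflecting the
plesiomorphy assumption appropriate to a ladderised tree with a designated
outgroup; `root_policy="free"` lifts the constraint. ACCTRAN and DELTRAN
are assigned by ordering reconstructions on the sorted depths of their
change branches: the lexicographically smallest profile (changes nearest
the root, hence favouring reversals) is ACCTRAN, the largest DELTRAN. This
selection rule provably labels actual MPRs and sidesteps the tie
ambiguities of uppass-based formulations on binary characters; when only
one MPR exists it carries both labels. An exhaustive 2^(internal nodes)
oracle verifies counts and scores for every possible binary leaf pattern
on the 8-taxon tree.

## Synthetic data: what it emulates, and what it does not

The generator emits LSC + IRb + SSC + revcomp(IRb) with per-region GC
targets (IR-high, SSC-low, as in real plastomes), planting SSRs, repeat
pairs, genes (ATG…stop, no internal stops) with one lesion each, and
editing sites whose pre-edit base is forced onto the coding strand. All
randomness flows from one integer seed through a single numpy generator,
so outputs are byte-identical across runs. Background sequence is scrubbed
so no unplanned tandem run reaches the reporting thresholds (accidental
dispersed repeats ≥ 30 bp at ≥ 90% identity are vanishingly unlikely at
this scale and are not scrubbed); guard bases pin planted SSR runs and the
IR boundaries so the planted coordinates are exactly maximal. Reads are
emitted pre-aligned (correct POS/CIGAR, all-match), sampled uniformly
within genes in proportion to RPKM target × gene length, with each
covering read edited independently with probability level/100 and a single
constant base quality. The default scale — 60 kb genome (30/10/10/10 kb
regions), six genes, 20,000 100 bp reads — runs in seconds.

What passing tests therefore show: the detectors recover planted truth
exactly under ideal alignment and error-free bases, and the editing caller
is statistically calibrated (levels within 3 binomial SD at ~200×). What
they do not show: robustness to alignment artefacts, indel sequencing
error, paralogy/multi-mapping ambiguity, or annotation errors in real
GFF3 — the pipeline's filters (uniqueness, quality, coverage) address
these but are exercised only at the unit level.

## Numerical and reporting conventions

Percentages are reported to the precision conventional for each table
(region GC 2 decimals, RSCU 2 decimals, family percentages 1 decimal, stop
shares integers). The pipeline report is a pure function of inputs,
configuration and seed apart from its timestamp field; thresholds in force
are echoed into the report for provenance. Problem sizes in the test suite
(genomes of 0.3–60 kb, read depths up to ~2,500×, trees of 8 taxa) were
chosen as desk-scale stand-ins that still exercise every code path,
including the brute-force oracles' validity ranges.

## Known limitations

- IR detection is exact-match only; a plastome whose IRs differ by even
  one base will report the longest exact sub-repeat instead. (Real IR
  pairs are usually identical; a mismatch-tolerant mode was deliberately
  left out to keep the maximality semantics crisp.)
- The dispersed-repeat scanner's maximality semantics report windows, not
  trimmed cores; consumers wanting REPuter-style exact cores should
  intersect windows with their mismatch positions.
- Compound SSR merging does not cross the circular origin.
- `classify_gene` assumes the reference CDS is correct and in frame;
  it does not discover loci (alignment-based locus discovery across
  genomes is out of scope — loci are inputs).
- The editing caller reports sites outside any CDS without codon context
  and ignores non-C/U substitutions by design.
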