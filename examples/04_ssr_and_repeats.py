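"""Scan a plastome for microsatellites and dispersed repeats.

Thresholds follow common plastome practice: mononucleotide runs of 7+,
di/tri of 4+, tetra-hexa of 3+ copies; dispersed repeat pairs of >= 30 bp
within a Hamming distance of 3 (>= 90% identity), forward or palindromic.
"""

from plastokit import classify_context, find_repeats, find_ssrs
from plastokit.synth import default_config, generate_plastome

genome, features, truth = generate_plastome(default_config(seed=1))

loci = classify_context(find_ssrs(genome), features, len(genome))
print(f"{len(loci)} SSR loci (planted: {len(truth.ssrs)}):")
for l in loci:
    ctx = l.context[0] if l.context else "?"
    print(f"  {l.motif:>5} x{l.copies:<3} {l.start:>6}..{l.end:<6} {ctx}")

pairs = find_repeats(genome)
print(f"{len(pairs)} dispersed repeat pairs (maximal windows, <= 3 mismatches):")
for p in pairs[:6]:
    print(f"  {p.kind:<12} {p.pos1} ~ {p.pos2}  {p.length} bp, "
          f"{p.mismatches} mm, {p.identity:.1f}% id")

# Motifs are reported as canonical classes (A/T runs both appear as "A";
# reverse-complement motifs share one class).  The largest palindromic pair
# is the inverted repeat itself; the others contain the planted copies,
# extended to maximality within the mismatch budget.
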