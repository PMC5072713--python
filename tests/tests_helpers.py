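"""Shared builders for planted test genomes."""

from __future__ import annotations

import numpy as np

from plastokit import PlastomeSeq
from plastokit._util import revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def planted_ir_genome(rng: np.random.Generator, lsc: int, ir: int,
                      ssc: int) -> tuple[PlastomeSeq, dict]:
    """LSC + IRb + SSC + revcomp(IRb), with the IR boundaries pinned so the
    inverted match cannot extend into the single-copy regions by chance."""
    lsc_seq = list(random_dna(rng, lsc))
    ir_seq = random_dna(rng, ir)
    ssc_seq = list(random_dna(rng, ssc))
    if lsc_seq[-1] == _COMP[lsc_seq[0]]:
        lsc_seq[-1] = [b for b in "ACGT" if b != _COMP[lsc_seq[0]]][0]
    if ssc_seq[0] == _COMP[ssc_seq[-1]]:
        ssc_seq[0] = [b for b in "ACGT" if b != _COMP[ssc_seq[-1]]][0]
    genome = "".join(lsc_seq) + ir_seq + "".join(ssc_seq) + revcomp(ir_seq)
    coords = {"lsc": (1, lsc), "irb": (lsc + 1, lsc + ir),
              "ssc": (lsc + ir + 1, lsc + ir + ssc),
              "ira": (lsc + ir + ssc + 1, lsc + 2 * ir + ssc)}
    return PlastomeSeq("planted", genome, circular=True), coords
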