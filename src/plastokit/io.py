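"""FASTA/GenBank input and simple table writers."""

from __future__ import annotations

import csv
from typing import Iterable

from Bio import SeqIO

from .structure import PlastomeSeq


def read_plastome(path, circular: bool = True) -> PlastomeSeq:
    """Read a single-record FASTA or GenBank file into a PlastomeSeq."""
    fmt = "genbank" if str(path).endswith((".gb", ".gbk", ".genbank")) else "fasta"
    records = list(SeqIO.parse(str(path), fmt))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one record, found {len(records)}")
    rec = records[0]
    return PlastomeSeq(id=rec.id, sequence=str(rec.seq).upper(), circular=circular)


def write_fasta(plastome: PlastomeSeq, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{plastome.id}\n")
        seq = plastome.sequence
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def write_tsv(rows: Iterable[dict], path, columns: list[str]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t",
                                extrasaction="ignore")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED rows.

    The coordinate conversion happens only here, at the writer boundary.
    """
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
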