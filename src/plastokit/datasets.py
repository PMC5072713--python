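"""Packaged reference tables for the U. reniformis plastome study system.

These are the published inputs the package's worked examples and acceptance
checks operate on: the 64-codon usage table with tRNA recognition
assignments, the annotated tRNA gene set, the ndh gene complex status/length
matrix across eight Lamiales taxa, their plastome lengths, and the species
tree topology.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .codons import CodonUsageTable, TrnaGene
from .parsimony import PhyloTree, parse_newick
from .pseudogenes import CharacterMatrix, GeneStatus, build_character_matrix

NDH_GENES = ("ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF",
             "ndhG", "ndhH", "ndhI", "ndhJ", "ndhK")


def _data_path(name: str):
    return resources.files("plastokit.data") / name


def codon_usage_table() -> pd.DataFrame:
    """The published codon usage table (counts, printed RSCU/percent, tRNA)."""
    return pd.read_csv(_data_path("ureniformis_codon_usage.tsv"), sep="\t",
                       comment="#")


def ureniformis_codon_counts() -> CodonUsageTable:
    df = codon_usage_table()
    return CodonUsageTable(dict(zip(df["codon"], df["count"])))


def trna_genes() -> list[TrnaGene]:
    df = pd.read_csv(_data_path("ureniformis_trna_genes.tsv"), sep="\t",
                     comment="#")
    return [TrnaGene(name=r["name"], anticodon=r["anticodon"], count=r["copies"])
            for _, r in df.iterrows()]


def ndh_complex() -> pd.DataFrame:
    """Long-format ndh gene status/length records across the eight taxa."""
    return pd.read_csv(_data_path("ndh_complex.tsv"), sep="\t", comment="#")


def ndh_taxa() -> list[str]:
    return list(dict.fromkeys(ndh_complex()["taxon"]))


def ndh_character_matrix() -> CharacterMatrix:
    """Binary presence matrix: 1 = intact, 0 = pseudogene or absent."""
    df = ndh_complex()
    statuses = []
    for _, r in df.iterrows():
        if r["status"] == "intact":
            status = GeneStatus(gene=r["gene"], taxon=r["taxon"], status="intact")
        elif r["status"] == "absent":
            status = GeneStatus(gene=r["gene"], taxon=r["taxon"], status="absent")
        else:
            status = GeneStatus(gene=r["gene"], taxon=r["taxon"],
                                status="pseudogene",
                                criteria=frozenset({"reported"}))
        statuses.append(status)
    return build_character_matrix(statuses, ndh_taxa(), list(NDH_GENES))


def plastome_lengths() -> dict[str, int]:
    df = pd.read_csv(_data_path("plastome_lengths.tsv"), sep="\t", comment="#")
    return dict(zip(df["taxon"], df["genome_bp"]))


def lentibulariaceae_tree() -> PhyloTree:
    with _data_path("lentibulariaceae.nwk").open() as fh:
        return parse_newick(fh.read())
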