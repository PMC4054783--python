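"""Plain-text readers and writers for the package's tabular formats.

Exon tables, codon alignments and SNP positions travel as TSV; ortholog
alignments can alternatively be supplied as peptide-alignment FASTA plus
CDS FASTA and back-translated on read.  Motif lists are handled by
:class:`~esekit.motif_sets.HexamerSet` itself.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO

from .sequence_model import (
    ExonRecord,
    OrthologExonPair,
    SNPTable,
    backtranslate_alignment,
)

_EXON_COLUMNS = [
    "gene_id", "exon_index", "exon_seq",
    "upstream_intron_seq", "downstream_intron_seq",
    "upstream_intron_len", "downstream_intron_len",
    "splice5_score", "splice3_score", "inclusion", "conservation",
]


def write_exons_tsv(exons, path) -> None:
    rows = []
    for e in exons:
        rows.append({c: getattr(e, c) for c in _EXON_COLUMNS})
    pd.DataFrame(rows, columns=_EXON_COLUMNS).to_csv(path, sep="\t", index=False)


def read_exons_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    exons = []
    for row in df.itertuples(index=False):
        kwargs = row._asdict()
        for key in ("splice5_score", "splice3_score"):
            if pd.isna(kwargs.get(key)):
                kwargs[key] = None
        for key in ("inclusion", "conservation"):
            if pd.isna(kwargs.get(key)):
                kwargs[key] = None
        for key in ("upstream_intron_seq", "downstream_intron_seq"):
            if pd.isna(kwargs.get(key)):
                kwargs[key] = ""
        exons.append(ExonRecord(**kwargs))
    return exons


def write_pairs_tsv(pairs, path) -> None:
    rows = [
        {
            "gene_id": p.gene_id,
            "exon_index": p.exon_index,
            "human_codons": " ".join(p.human_codons),
            "mouse_codons": " ".join(p.mouse_codons),
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return [
        OrthologExonPair(
            row.gene_id,
            int(row.exon_index),
            tuple(row.human_codons.split()),
            tuple(row.mouse_codons.split()),
        )
        for row in df.itertuples(index=False)
    ]


def write_snps_tsv(snps: SNPTable, path) -> None:
    rows = [
        {"exon_id": exon_id, "offset": off}
        for exon_id in snps.exon_ids()
        for off in sorted(snps.get(exon_id))
    ]
    pd.DataFrame(rows, columns=["exon_id", "offset"]).to_csv(
        path, sep="\t", index=False
    )


def read_snps_tsv(path) -> SNPTable:
    df = pd.read_csv(path, sep="\t", dtype={"exon_id": str})
    table = SNPTable()
    for row in df.itertuples(index=False):
        table.add(row.exon_id, int(row.offset))
    return table


def read_ortholog_alignments(
    peptide_fasta, cds_human_fasta, cds_mouse_fasta,
) -> list:
    """Back-translate paired peptide alignments onto their CDSs.

    The peptide FASTA holds two aligned records per gene, identified as
    ``<gene>|human`` and ``<gene>|mouse``; the CDS FASTAs are keyed by
    gene id.  Returns one codon-alignment pair per gene.
    """
    peptides: dict = {}
    for rec in SeqIO.parse(str(peptide_fasta), "fasta"):
        gene, _, species = rec.id.partition("|")
        peptides.setdefault(gene, {})[species] = str(rec.seq)
    cds_h = {r.id: str(r.seq) for r in SeqIO.parse(str(cds_human_fasta), "fasta")}
    cds_m = {r.id: str(r.seq) for r in SeqIO.parse(str(cds_mouse_fasta), "fasta")}
    pairs = []
    for gene in sorted(peptides):
        rows = peptides[gene]
        if set(rows) != {"human", "mouse"}:
            raise ValueError(f"{gene}: need exactly a human and a mouse row")
        pairs.append(
            backtranslate_alignment(
                rows["human"], rows["mouse"], cds_h[gene], cds_m[gene], gene_id=gene
            )
        )
    return pairs


def read_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="exon_id")
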