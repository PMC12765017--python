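"""File-format front doors: counts TSV, GMT gene sets, VCF, MAF-like TSV,
fusion tables, protein FASTA and clinical CSV.

VCFs are read and written through pysam with ``DP``/``AD`` FORMAT fields
and simple INFO tags for the annotated gene, consequence, protein change
and transcript.  The MAF-like table keeps a fixed, versioned column order
so cohort diffs stay reproducible.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .fusions import FusionCall
from .variants import VariantRecord

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_gmt",
    "write_gmt",
    "read_vcf",
    "write_vcf",
    "MAF_COLUMNS",
    "read_maf",
    "write_maf",
    "read_fusions_tsv",
    "write_fusions_tsv",
    "read_fasta",
    "write_fasta",
    "read_clinical_csv",
    "write_clinical_csv",
    "read_signature_catalog",
]

MAF_COLUMNS = (
    "sample", "gene", "chrom", "pos", "ref", "alt",
    "consequence", "HGVSp", "t_depth", "t_alt_count",
)


def read_counts_tsv(path, lengths_path=None) -> ExpressionMatrix:
    """Counts TSV: genes as rows, header row of sample ids.  An optional
    two-column TSV (gene, length) supplies gene lengths."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = None
    if lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
        lengths = lt.reindex(df.index).to_numpy(dtype=float)
    return ExpressionMatrix(
        counts=df.to_numpy(),
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        gene_lengths=lengths,
    )


def write_counts_tsv(mat: ExpressionMatrix, path) -> None:
    mat.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_gmt(path) -> dict:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path, descriptions: dict = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, name)
            fh.write("\t".join([name, desc, *genes]) + "\n")


def _vcf_header(contigs: dict):
    import pysam

    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.info.add("GENE", 1, "String", "Annotated gene symbol")
    header.info.add("CSQ", 1, "String", "Consequence term")
    header.info.add("HGVSP", 1, "String", "Protein change")
    header.info.add("TX", 1, "String", "Transcript id")
    header.filters.add("germline", None, None, "Matched germline evidence")
    return header


def write_vcf(records: Iterable[VariantRecord], path, contigs: dict, source: str = None) -> None:
    """Write per-sample VCF 4.2 text with DP/AD FORMAT fields.

    ``contigs`` maps contig name -> length.  All samples present in the
    records become VCF sample columns; DP/AD are set on the record's own
    sample.
    """
    import pysam

    records = list(records)
    samples = sorted({r.sample_id for r in records})
    header = _vcf_header(contigs)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in sorted(records, key=lambda v: (v.chrom, v.pos, v.ref, v.alt, v.sample_id)):
            rec = vf.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt)
            )
            for f in r.filter_status:
                rec.filter.add(f if f != "." else "PASS")
            if r.gene_id:
                rec.info["GENE"] = r.gene_id
            if r.consequence:
                rec.info["CSQ"] = r.consequence
            if r.hgvsp:
                rec.info["HGVSP"] = r.hgvsp
            if r.transcript_id:
                rec.info["TX"] = r.transcript_id
            if r.depth is not None:
                rec.samples[r.sample_id]["DP"] = r.depth
            if r.alt_count is not None and r.depth is not None:
                rec.samples[r.sample_id]["AD"] = (r.depth - r.alt_count, r.alt_count)
            vf.write(rec)


def read_vcf(path, source: str = "wes_tumor") -> list:
    """Read a VCF written by :func:`write_vcf` back into VariantRecords
    (one record per sample column carrying depth at each site)."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            filters = frozenset(rec.filter.keys()) or frozenset({"PASS"})
            for sample in rec.samples:
                fmt = rec.samples[sample]
                dp = fmt.get("DP")
                if dp is None:
                    continue
                ad = fmt.get("AD")
                alt_count = int(ad[1]) if ad is not None and ad[1] is not None else None
                out.append(
                    VariantRecord(
                        sample_id=sample,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=rec.alts[0],
                        filter_status=filters,
                        depth=int(dp),
                        alt_count=alt_count,
                        consequence=rec.info.get("CSQ", ""),
                        gene_id=rec.info.get("GENE", ""),
                        transcript_id=rec.info.get("TX", ""),
                        hgvsp=rec.info.get("HGVSP", ""),
                        source=source,
                    )
                )
    return out


def write_maf(records: Iterable[VariantRecord], path) -> None:
    rows = [
        {
            "sample": r.sample_id, "gene": r.gene_id, "chrom": r.chrom, "pos": r.pos,
            "ref": r.ref, "alt": r.alt, "consequence": r.consequence, "HGVSp": r.hgvsp,
            "t_depth": r.depth, "t_alt_count": r.alt_count,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(MAF_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_maf(path, source: str = "wes_tumor") -> list:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            VariantRecord(
                sample_id=row["sample"], chrom=str(row["chrom"]), pos=int(row["pos"]),
                ref=row["ref"], alt=row["alt"], consequence=row.get("consequence", ""),
                gene_id=row.get("gene", ""), hgvsp=row.get("HGVSp", "") or "",
                depth=None if pd.isna(row.get("t_depth")) else int(row["t_depth"]),
                alt_count=None if pd.isna(row.get("t_alt_count")) else int(row["t_alt_count"]),
                source=source,
            )
        )
    return out


def write_fusions_tsv(calls: Iterable[FusionCall], path) -> None:
    rows = [
        {
            "sample": c.sample_id, "gene_5p": c.gene_5p, "gene_3p": c.gene_3p,
            "junction_reads": c.junction_reads, "spanning_frags": c.spanning_frags,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=["sample", "gene_5p", "gene_3p", "junction_reads", "spanning_frags"]).to_csv(
        path, sep="\t", index=False
    )


def read_fusions_tsv(path, column_map: dict = None) -> list:
    """Fusion table reader; ``column_map`` renames caller-style columns to
    the canonical sample/gene_5p/gene_3p/junction_reads/spanning_frags."""
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    return [
        FusionCall(
            sample_id=row["sample"], gene_5p=row["gene_5p"], gene_3p=row["gene_3p"],
            junction_reads=int(row.get("junction_reads", 0)),
            spanning_frags=int(row.get("spanning_frags", 0)),
        )
        for _, row in df.iterrows()
    ]


def read_fasta(path) -> dict:
    """FASTA id -> sequence (Biopython)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_clinical_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_clinical_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_signature_catalog(path) -> pd.DataFrame:
    """Reference signature catalog TSV: 96 channel rows x named columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise ValueError(f"catalog must have 96 rows (got {df.shape[0]})")
    return df
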