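"""Readers and writers for the formats the pipeline touches.

VCF is read with cyvcf2 (1-based positions converted to 0-based at this
boundary, once); BED and GFF3 are read with pyranges.  The canonical
interchange for read observations is a headered TSV, so the core
pipeline has no binary-format dependency; a BAM adapter (pysam) can
produce the same observations from alignments.
"""

from __future__ import annotations

import hashlib
import logging
import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .asm import CGIRecord
from .haplotyping import MISSING, PhasedVariant, ReadObservation
from .methylation import CpGCall

__all__ = [
    "read_phased_vcf",
    "write_phased_vcf",
    "read_observations_tsv",
    "write_observations_tsv",
    "read_cgi_bed",
    "write_cgi_bed",
    "read_gene_model_gff3",
    "write_gene_model_gff3",
    "write_calls_bed",
    "read_calls_bed",
    "bam_to_observations",
    "write_dataset",
    "file_checksum",
]

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_phased_vcf(path) -> list[PhasedVariant]:
    """Load phased heterozygous biallelic SNVs from a VCF.

    Keeps records with a single REF/ALT base each and a phased
    heterozygous genotype (0|1 or 1|0) on the first sample.  The
    haplotype-A allele is the one on the first phase strand.  Skipped
    records (indels, multi-allelic, unphased, homozygous) are counted
    and logged.
    """
    from cyvcf2 import VCF

    variants: list[PhasedVariant] = []
    skipped = {"indel_or_mnp": 0, "multiallelic": 0, "unphased": 0, "not_het": 0}
    vcf = VCF(str(path))
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            skipped["indel_or_mnp"] += 1
            continue
        gt = rec.genotypes[0]  # [allele0, allele1, phased]
        if not gt[-1]:
            skipped["unphased"] += 1
            continue
        a0, a1 = gt[0], gt[1]
        if {a0, a1} != {0, 1}:
            skipped["not_het"] += 1
            continue
        allele_a = ref if a0 == 0 else alt
        allele_b = alt if a0 == 0 else ref
        variants.append(
            PhasedVariant(
                chrom=rec.CHROM,
                pos=rec.POS - 1,  # 1-based VCF -> 0-based internal
                allele_a=allele_a,
                allele_b=allele_b,
            )
        )
    vcf.close()
    total_skipped = sum(skipped.values())
    if total_skipped:
        logger.warning("skipped %d VCF records: %s", total_skipped, skipped)
    if not variants:
        logger.warning("no phased heterozygous SNVs found in %s", path)
    return variants


def write_phased_vcf(variants: Iterable[PhasedVariant], path) -> None:
    """Write variants as a minimal VCF with one sample, GT 0|1.

    REF is the haplotype-A allele and ALT the haplotype-B allele, so
    reading the file back reproduces the phasing exactly.
    """
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({v.chrom for v in variants}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.allele_a}\t{v.allele_b}"
                f"\t.\tPASS\t.\tGT\t0|1\n"
            )


# ---------------------------------------------------------------------------
# read observations TSV
# ---------------------------------------------------------------------------


def _encode_phv(phv_bases: dict) -> str:
    return ";".join(f"{int(p)}:{b}" for p, b in sorted(phv_bases.items()))


def _encode_ipd(cpg_ipd: dict) -> str:
    return ";".join(
        f"{int(p)}:" + ",".join(repr(float(v)) for v in values)
        for p, values in sorted(cpg_ipd.items())
    )


def write_observations_tsv(reads: Iterable[ReadObservation], path) -> None:
    """Write reads as the canonical observation TSV.

    Columns: read_id, chrom, start, end, phv_obs (``pos:base;...``),
    cpg_ipd (``pos:v1,v2;...``).  Floats use the shortest exact
    representation so write-then-read is lossless.
    """
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tend\tphv_obs\tcpg_ipd\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.chrom}\t{r.start}\t{r.end}\t"
                f"{_encode_phv(r.phv_bases)}\t{_encode_ipd(r.cpg_ipd)}\n"
            )


def read_observations_tsv(path) -> list[ReadObservation]:
    """Read the canonical observation TSV back into objects."""
    reads = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["read_id", "chrom", "start", "end", "phv_obs", "cpg_ipd"]
        if header != expected:
            raise ValueError(f"unexpected observation TSV header: {header}")
        for line in fh:
            read_id, chrom, start, end, phv_s, ipd_s = line.rstrip("\n").split("\t")
            phv_bases = {}
            if phv_s:
                for item in phv_s.split(";"):
                    p, b = item.split(":")
                    phv_bases[int(p)] = b
            cpg_ipd = {}
            if ipd_s:
                for item in ipd_s.split(";"):
                    p, vals = item.split(":")
                    cpg_ipd[int(p)] = [float(v) for v in vals.split(",")]
            reads.append(
                ReadObservation(
                    read_id=read_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    phv_bases=phv_bases,
                    cpg_ipd=cpg_ipd,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# BED / GFF3
# ---------------------------------------------------------------------------


def read_cgi_bed(path) -> list[CGIRecord]:
    """Read CpG islands from BED.

    Column 4 (name) becomes the island id; column 5 (score), when
    present, is taken as the CpG count — the convention used by this
    package's writer.  Without a score column the CpG count is 0 and
    must be supplied downstream.
    """
    import pyranges as pr

    df = pr.read_bed(str(path), as_df=True)
    records = []
    for i, row in df.iterrows():
        name = str(row["Name"]) if "Name" in df.columns else f"CGI_{i:04d}"
        n_cpg = int(row["Score"]) if "Score" in df.columns else 0
        records.append(
            CGIRecord(
                chrom=str(row["Chromosome"]),
                start=int(row["Start"]),
                end=int(row["End"]),
                n_cpg=n_cpg,
                id=name,
            )
        )
    return records


def write_cgi_bed(cgis: Iterable[CGIRecord], path) -> None:
    """Write islands as BED with name = id and score = CpG count."""
    with open(path, "w") as fh:
        for c in sorted(cgis, key=lambda c: (c.chrom, c.start)):
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.id}\t{c.n_cpg}\t+\n")


def write_gene_model_gff3(
    genes: pd.DataFrame, exons: pd.DataFrame, path, chrom: str = "chr1"
) -> None:
    """Write a minimal GFF3 gene model (gene and exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{chrom}\tdiplomethyl\tgene\t{g['start'] + 1}\t{g['end']}\t.\t+\t.\t"
                f"ID={g['gene_id']}\n"
            )
            gene_exons = exons[exons["gene_id"] == g["gene_id"]]
            for j, (_, e) in enumerate(gene_exons.iterrows()):
                fh.write(
                    f"{chrom}\tdiplomethyl\texon\t{e['start'] + 1}\t{e['end']}\t.\t+\t.\t"
                    f"ID={g['gene_id']}.exon{j};Parent={g['gene_id']}\n"
                )


def read_gene_model_gff3(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read gene and exon intervals from GFF3 (0-based half-open out).

    Returns ``(genes, exons)`` DataFrames with columns
    chrom, gene_id, start, end.
    """
    import pyranges as pr

    df = pr.read_gff3(str(path), as_df=True)
    if df.empty:
        raise ValueError(f"no features parsed from {path}")

    def _gene_id(row):
        if "Parent" in df.columns and isinstance(row.get("Parent"), str) and row["Parent"]:
            return row["Parent"]
        return row.get("ID", "")

    genes_df = df[df["Feature"] == "gene"]
    exons_df = df[df["Feature"] == "exon"]
    genes = pd.DataFrame(
        {
            "chrom": genes_df["Chromosome"].astype(str),
            "gene_id": genes_df["ID"].astype(str),
            "start": genes_df["Start"].astype(int),
            "end": genes_df["End"].astype(int),
        }
    ).reset_index(drop=True)
    exons = pd.DataFrame(
        {
            "chrom": exons_df["Chromosome"].astype(str),
            "gene_id": [_gene_id(r) for _, r in exons_df.iterrows()],
            "start": exons_df["Start"].astype(int),
            "end": exons_df["End"].astype(int),
        }
    ).reset_index(drop=True)
    return genes, exons


# ---------------------------------------------------------------------------
# methylation calls
# ---------------------------------------------------------------------------


def write_calls_bed(calls: Iterable[CpGCall], path) -> None:
    """Write per-CpG calls as a BED-like TSV.

    Columns: chrom, pos, pos+2 (the CpG dinucleotide), haplotype, state,
    coverage.
    """
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\thaplotype\tstate\tcoverage\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.pos + 2}\t{c.haplotype}\t{c.state}\t"
                f"{c.coverage}\n"
            )


def read_calls_bed(path) -> list[CpGCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        CpGCall(
            chrom=str(r.chrom),
            pos=int(r.start),
            haplotype=str(r.haplotype),
            state=str(r.state),
            coverage=int(r.coverage),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# BAM adapter
# ---------------------------------------------------------------------------


def bam_to_observations(
    bam_path,
    variants: Sequence[PhasedVariant],
    cpg_sites: Sequence[int] | None = None,
) -> list[ReadObservation]:
    """Extract observation records from a coordinate-sorted BAM/SAM.

    For each primary alignment, reports the aligned base at every
    covered phased-variant position; a variant position deleted in the
    read is reported as MISSING.  Kinetic (IPD) values are not carried
    by standard alignments, so ``cpg_ipd`` is left empty — kinetics
    enter through the observation TSV produced by the platform pipeline.
    """
    import pysam

    by_chrom: dict[str, set[int]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, set()).add(v.pos)

    reads = []
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for aln in bam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            wanted = by_chrom.get(aln.reference_name, set())
            phv_bases: dict[int, str] = {}
            if wanted:
                seq = aln.query_sequence or ""
                for qpos, rpos in aln.get_aligned_pairs():
                    if rpos is None or rpos not in wanted:
                        continue
                    phv_bases[rpos] = seq[qpos].upper() if qpos is not None else MISSING
            reads.append(
                ReadObservation(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    phv_bases=phv_bases,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# dataset emission, checksums
# ---------------------------------------------------------------------------


def write_dataset(dataset, out_dir) -> dict[str, str]:
    """Write a SimulatedDataset's files; returns name -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants_vcf": out_dir / "variants.vcf",
        "cgi_bed": out_dir / "cgi.bed",
        "gene_model_gff3": out_dir / "genes.gff3",
        "reads_tsv": out_dir / "reads.tsv",
        "rna_tsv": out_dir / "rna_observations.tsv",
        "truth_reads": out_dir / "truth_read_haplotypes.tsv",
        "truth_cpgs": out_dir / "truth_cpg_states.tsv",
        "truth_cgis": out_dir / "truth_cgi_asm.tsv",
    }
    write_phased_vcf(dataset.variants, paths["variants_vcf"])
    cgis = [
        CGIRecord(
            chrom=r.chrom, start=int(r.start), end=int(r.end),
            n_cpg=int(r.n_cpg), id=str(r.cgi_id),
        )
        for r in dataset.cgis.itertuples()
    ]
    write_cgi_bed(cgis, paths["cgi_bed"])
    write_gene_model_gff3(
        dataset.genes, dataset.exons, paths["gene_model_gff3"],
        chrom=dataset.spec.chrom,
    )
    write_observations_tsv(dataset.reads, paths["reads_tsv"])
    dataset.rna_observations.to_csv(paths["rna_tsv"], sep="\t", index=False)
    dataset.truth.read_haplotypes.to_csv(paths["truth_reads"], sep="\t", index=False)
    dataset.truth.cpg_states.to_csv(paths["truth_cpgs"], sep="\t", index=False)
    dataset.truth.cgi_asm.to_csv(paths["truth_cgis"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def file_checksum(path) -> str:
    """SHA-256 of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
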