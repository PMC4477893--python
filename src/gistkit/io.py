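"""Readers and writers for the flat-file formats the pipeline exchanges.

Variant tables travel either as a flat TSV (one column per
:class:`~gistkit.filters.VariantRecord` field) or as a minimal VCF v4.2
with two samples, ``TUMOUR`` and ``CONTROL``, carrying per-sample FORMAT
fields ``DP`` (depth), ``ADF``/``ADR`` (alt-allele reads on the
forward/reverse strand).  The control's strand split is not modelled: its
alt count is stored in ``ADF`` and recovered as ``ADF + ADR`` on read.
Annotations ride in INFO fields ``VC`` (variant class), ``RC`` (region),
``EC`` (effect) and ``SNP`` (known-SNP id).

SNP BAF tables, chromosome-arm definitions (BED-like, half-open 0-based),
screen panels and methylation matrices are plain TSV; proteins are FASTA.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import pysam
from Bio import SeqIO

from .filters import VariantRecord, records_from_frame, records_to_frame
from .loh import SNP_COLUMNS

__all__ = [
    "read_variant_tsv",
    "write_variant_tsv",
    "read_variant_vcf",
    "write_variant_vcf",
    "read_snp_tsv",
    "write_snp_tsv",
    "read_arm_bed",
    "assign_arms",
    "read_screen_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_reference_tsv",
    "read_fasta",
    "read_protein_variants_tsv",
]


# -- variant tables ---------------------------------------------------------

def read_variant_tsv(path) -> list[VariantRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return records_from_frame(frame)


def write_variant_tsv(records: Sequence[VariantRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, na_rep="")


_VCF_HEADER_LINES = [
    '##INFO=<ID=VC,Number=1,Type=String,Description="Variant class">',
    '##INFO=<ID=RC,Number=1,Type=String,Description="Region class">',
    '##INFO=<ID=EC,Number=1,Type=String,Description="Effect class">',
    '##INFO=<ID=SNP,Number=1,Type=String,Description="Known SNP identifier">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=ADF,Number=1,Type=Integer,Description="Alt reads, forward strand">',
    '##FORMAT=<ID=ADR,Number=1,Type=Integer,Description="Alt reads, reverse strand">',
]


def write_variant_vcf(records: Sequence[VariantRecord], path) -> None:
    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    for chrom in dict.fromkeys(r.chrom for r in records):
        header.contigs.add(chrom)
    for sample in ("TUMOUR", "CONTROL"):
        header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in records:
            rec = vcf.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                alleles=(r.ref_allele, r.alt_allele),
            )
            rec.info["VC"] = r.variant_class
            rec.info["RC"] = r.region_class
            rec.info["EC"] = r.effect_class
            if r.known_snp_id:
                rec.info["SNP"] = r.known_snp_id
            rec.samples["TUMOUR"]["DP"] = r.tumour_depth
            rec.samples["TUMOUR"]["ADF"] = r.tumour_alt_fwd
            rec.samples["TUMOUR"]["ADR"] = r.tumour_alt_rev
            rec.samples["CONTROL"]["DP"] = r.control_depth
            rec.samples["CONTROL"]["ADF"] = r.control_alt_count
            rec.samples["CONTROL"]["ADR"] = 0
            vcf.write(rec)


def _fmt(sample, key) -> int:
    value = sample.get(key)
    if value is None:
        raise ValueError(f"missing FORMAT field {key}")
    return int(value)


def read_variant_vcf(path) -> list[VariantRecord]:
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            tumour = rec.samples["TUMOUR"]
            control = rec.samples["CONTROL"]
            out.append(
                VariantRecord(
                    chrom=rec.contig,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0] if rec.alts else ".",
                    tumour_alt_fwd=_fmt(tumour, "ADF"),
                    tumour_alt_rev=_fmt(tumour, "ADR"),
                    tumour_depth=_fmt(tumour, "DP"),
                    control_alt_count=_fmt(control, "ADF") + _fmt(control, "ADR"),
                    control_depth=_fmt(control, "DP"),
                    variant_class=rec.info.get("VC", "SNV"),
                    region_class=rec.info.get("RC", "exonic-coding"),
                    effect_class=rec.info.get("EC", "unknown"),
                    known_snp_id=rec.info.get("SNP", None),
                )
            )
    return out


# -- SNP BAF tables and arm definitions -------------------------------------

def read_snp_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "arm": str})
    missing = set(SNP_COLUMNS) - set(frame.columns)
    if missing - {"arm"}:
        raise ValueError(f"SNP table lacks columns: {sorted(missing - {'arm'})}")
    return frame


def write_snp_tsv(snps: pd.DataFrame, path) -> None:
    snps.to_csv(path, sep="\t", index=False)


def read_arm_bed(path) -> pd.DataFrame:
    """Chromosome-arm intervals: columns chrom, start, end, arm (0-based,
    half-open)."""
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "arm"],
        dtype={"chrom": str, "arm": str},
        comment="#",
    )
    if (frame["end"] <= frame["start"]).any():
        raise ValueError("arm intervals must satisfy start < end")
    return frame


def assign_arms(snps: pd.DataFrame, arms: pd.DataFrame) -> pd.DataFrame:
    """Attach an ``arm`` column to a SNP table from interval definitions.

    A SNP at 1-based position ``pos`` falls in the half-open 0-based
    interval ``[start, end)``; unassigned SNPs are dropped.
    """
    out = snps.copy()
    labels = pd.Series(pd.NA, index=out.index, dtype=object)
    for row in arms.itertuples(index=False):
        hit = (
            (out["chrom"] == row.chrom)
            & (out["pos"] - 1 >= row.start)
            & (out["pos"] - 1 < row.end)
        )
        labels[hit] = row.arm
    out["arm"] = labels
    return out.dropna(subset=["arm"]).reset_index(drop=True)


# -- screen panel ------------------------------------------------------------

def read_screen_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"maf": str})


# -- methylation matrices ----------------------------------------------------

def read_matrix_tsv(path) -> pd.DataFrame:
    """Probes × samples matrix; first column holds probe identifiers."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_reference_tsv(path) -> pd.DataFrame:
    """Per-probe reference signals: columns probe_id, ref_low, ref_high."""
    frame = pd.read_csv(path, sep="\t")
    required = {"probe_id", "ref_low", "ref_high"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"reference table lacks columns: {sorted(missing)}")
    return frame.set_index("probe_id")


# -- proteins ----------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_protein_variants_tsv(path) -> pd.DataFrame:
    """Protein variants: columns seq_id plus either an ``hgvs`` shorthand
    column (e.g. Arg1038Trp) or explicit position/ref_aa/alt_aa columns."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "seq_id" not in frame.columns:
        raise ValueError("protein variant table needs a seq_id column")
    has_hgvs = "hgvs" in frame.columns
    has_explicit = {"position", "ref_aa", "alt_aa"} <= set(frame.columns)
    if not (has_hgvs or has_explicit):
        raise ValueError(
            "protein variant table needs an hgvs column or position/ref_aa/alt_aa"
        )
    return frame
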