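"""File-format plumbing: FASTQ/FASTA/TSV/VCF readers and audited TSV output."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .cohort import SampleProfile, call_gene_status
from .pipeline import MergedRead

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "consequence"]


def read_fastq(path) -> list[MergedRead]:
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            MergedRead(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                quality=list(rec.letter_annotations.get("phred_quality", [])) or None,
            )
        )
    return reads


def read_sample_table(path) -> pd.DataFrame:
    """Samples-by-columns TSV with a sample_id index (exposures, expression)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index(df.columns[0])
    df.index.name = "sample_id"
    return df


def read_variant_table(path) -> pd.DataFrame:
    """Variant records from TSV (preferred) or VCF.

    TSV columns: chrom, pos, ref, alt, consequence plus optional sample_id and
    gene columns.  For VCF input, consequence/gene/sample are taken from the
    CONSEQUENCE / GENE / SAMPLE INFO keys when present.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    return df


def _read_vcf(path: Path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": alt,
                        "consequence": rec.info.get("CONSEQUENCE", "other"),
                        "gene": rec.info.get("GENE", ""),
                        "sample_id": rec.info.get("SAMPLE", ""),
                    }
                )
    return pd.DataFrame(rows)


def build_profiles(
    exposures: pd.DataFrame,
    expression: pd.DataFrame,
    variants: pd.DataFrame | None = None,
    genes: Sequence[str] | None = None,
) -> list[SampleProfile]:
    """Join the three tables into SampleProfiles on matching sample ids."""
    samples = exposures.index.intersection(expression.index)
    statuses: dict[str, dict[str, str]] = {}
    if variants is not None and not variants.empty:
        if "sample_id" not in variants.columns or "gene" not in variants.columns:
            raise ValueError("variant table needs sample_id and gene columns")
        gene_set = set(genes) if genes else set(variants["gene"])
        for (sid, gene), sub in variants.groupby(["sample_id", "gene"]):
            if gene in gene_set:
                statuses.setdefault(str(sid), {})[str(gene)] = call_gene_status(
                    sub["consequence"].tolist()
                )
    profiles = []
    for sid in samples:
        status = {g: "wildtype" for g in (genes or [])}
        status.update(statuses.get(str(sid), {}))
        profiles.append(
            SampleProfile(
                sample_id=str(sid),
                exposures=exposures.loc[sid].to_dict(),
                gene_status=status,
                expression=expression.loc[sid].to_dict(),
            )
        )
    return profiles


def write_tsv(df: pd.DataFrame, path, params: dict | None = None, index=True) -> None:
    """TSV with '#' header comments recording version and run parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# polq-scars {__version__}\n")
        for key, value in (params or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
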