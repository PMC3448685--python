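"""Readers and writers for the formats the pipeline touches.

Formats: VCF (v4.x, GT field) and dosage TSV for genotypes; TSV for
expression, covariates and result tables; BED (3+ columns, 0-based
half-open) for pri-miRNA and 3'UTR intervals; TSV with 1-based inclusive
coordinates for probe annotations.  All result files are tab-separated with
a header row.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (
    PROBE_QUALITY_VOCABULARY,
    AnnotationSet,
    CovariateTable,
    ExpressionMatrix,
    GenomicInterval,
    GenotypeMatrix,
    ProbeAnnotation,
    SnpRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_dosage_tsv",
    "write_snp_table",
    "write_vcf",
    "read_expression",
    "write_expression",
    "read_covariates",
    "write_covariates",
    "read_annotations",
    "read_bed",
    "write_bed",
    "write_probe_table",
    "write_results",
    "read_results",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line or record."""


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _orient_minor(alt_dosage: np.ndarray, ref: str, alt: str) -> tuple[np.ndarray, str, str]:
    """Orient dosages to count the minor allele.

    The minor allele is the one with the lower observed frequency; an exact
    tie is broken by taking the alphabetically-first allele as minor.
    """
    called = alt_dosage[~np.isnan(alt_dosage)]
    alt_freq = called.mean() / 2.0 if called.size else 0.0
    if alt_freq < 0.5:
        minor_is_alt = True
    elif alt_freq > 0.5:
        minor_is_alt = False
    else:  # tie: alphabetically-first allele is minor
        minor_is_alt = alt <= ref
    if minor_is_alt:
        return alt_dosage, ref, alt
    return 2.0 - alt_dosage, alt, ref


def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    snp_table: str | Path | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or a dosage TSV.

    Dosages count copies of the dataset-minor allele; missing genotypes are
    preserved as NaN.  Multiallelic VCF records are rejected.

    Parameters
    ----------
    path : path
        VCF file (``format="vcf"``) or dosage TSV (``format="dosage_tsv"``,
        samples in rows, SNPs in columns, first column ``sample_id``).
    snp_table : path, optional
        For ``dosage_tsv``: companion TSV with columns
        ``snp_id  chrom  pos  major  minor`` (``pos`` 1-based).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path, snp_table)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ParseError(f"{path}: duplicated sample ids")
    cols: dict[str, np.ndarray] = {}
    records: dict[str, SnpRecord] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            raise ParseError(
                f"{path}: multiallelic record at {var.CHROM}:{var.POS} "
                f"({var.REF}->{var.ALT}); only biallelic records are supported"
            )
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        if snp_id in cols:
            raise ParseError(f"{path}: duplicated SNP id {snp_id}")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        alt_dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        dos, major, minor = _orient_minor(alt_dos, var.REF, var.ALT[0])
        cols[snp_id] = dos
        called = dos[~np.isnan(dos)]
        maf = float(called.mean() / 2.0) if called.size else float("nan")
        records[snp_id] = SnpRecord(
            snp_id=snp_id, chrom=var.CHROM, pos=var.POS - 1,
            major=major, minor=minor, maf=maf,
        )
    df = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
    return GenotypeMatrix(df, records)


def _read_dosage_tsv(path: Path, snp_table: str | Path | None) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
    except Exception as exc:  # re-raise naming the file
        raise ParseError(f"{path}: {exc}") from exc
    records: dict[str, SnpRecord] = {}
    if snp_table is not None:
        meta = pd.read_csv(snp_table, sep="\t")
        for row in meta.itertuples(index=False):
            records[row.snp_id] = SnpRecord(
                snp_id=row.snp_id, chrom=str(row.chrom), pos=int(row.pos) - 1,
                major=str(row.major), minor=str(row.minor),
                maf=float(getattr(row, "maf", float("nan"))),
            )
        records = {k: v for k, v in records.items() if k in df.columns}
    return GenotypeMatrix(df, records)


def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as TSV (samples x SNPs); missing written as empty."""
    G.dosages.to_csv(path, sep="\t", index_label="sample_id", float_format="%.0f")


def write_snp_table(G: GenotypeMatrix, path: str | Path) -> None:
    """Write the SNP metadata companion table (1-based positions)."""
    rows = [
        {
            "snp_id": r.snp_id, "chrom": r.chrom, "pos": r.pos1,
            "major": r.major, "minor": r.minor, "maf": r.maf,
        }
        for r in G.snps.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT genotypes (REF=major, ALT=minor)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, G.sample_ids)) + "\n")
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        order = sorted(
            G.snp_ids,
            key=lambda s: (G.snps[s].chrom, G.snps[s].pos) if s in G.snps else ("", 0),
        )
        for snp_id in order:
            rec = G.snps.get(snp_id) or SnpRecord(snp_id, "NA", 0)
            dos = G.dosages[snp_id].to_numpy()
            gts = "\t".join(
                "./." if np.isnan(d) else gt_codes[d] for d in dos
            )
            fh.write(
                f"{rec.chrom}\t{rec.pos1}\t{snp_id}\t{rec.major}\t{rec.minor}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# expression / covariates
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a samples x probes expression TSV (first column ``sample_id``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return ExpressionMatrix(df)


def write_expression(E: ExpressionMatrix, path: str | Path) -> None:
    E.values.to_csv(path, sep="\t", index_label="sample_id")


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return CovariateTable(df)


def write_covariates(C: CovariateTable, path: str | Path) -> None:
    C.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> dict[str, GenomicInterval]:
    """Read a BED (3+ columns) into name -> interval.

    BED is 0-based half-open, matching the internal convention, so no
    conversion happens.  Unnamed lines get ``chrom:start-end`` keys.
    """
    out: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{i}: expected >=3 BED columns")
            chrom, s, e = parts[0], parts[1], parts[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{i}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 and parts[3] else f"{chrom}:{start}-{end}"
            if name in out:
                raise ParseError(f"{path}:{i}: duplicated interval name {name!r}")
            out[name] = GenomicInterval(chrom, start, end)
    return out


def write_bed(intervals: dict[str, GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, iv in intervals.items():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_probe_table(path: str | Path) -> dict[str, ProbeAnnotation]:
    """Read probe annotations (TSV, 1-based inclusive ``start``/``end``).

    Columns: ``probe_id gene chrom start end quality contains_snp``.
    Unknown quality flags are kept with a warning; rows with missing
    quality/contains_snp are excluded (logged).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    probes: dict[str, ProbeAnnotation] = {}
    for row in df.itertuples(index=False):
        if pd.isna(row.quality) or pd.isna(row.contains_snp):
            logger.warning("probe %s: missing quality flags, excluded", row.probe_id)
            continue
        quality = str(row.quality)
        if quality not in PROBE_QUALITY_VOCABULARY:
            warnings.warn(f"probe {row.probe_id}: unknown quality flag {quality!r}")
        probes[str(row.probe_id)] = ProbeAnnotation(
            probe_id=str(row.probe_id),
            gene=str(row.gene),
            interval=GenomicInterval.from_1based(str(row.chrom), int(row.start), int(row.end)),
            quality=quality,
            contains_snp=bool(row.contains_snp),
        )
    return probes


def write_probe_table(probes: dict[str, ProbeAnnotation], path: str | Path) -> None:
    rows = []
    for ann in probes.values():
        chrom, s1, e1 = ann.interval.to_1based()
        rows.append(
            {
                "probe_id": ann.probe_id, "gene": ann.gene, "chrom": chrom,
                "start": s1, "end": e1, "quality": ann.quality,
                "contains_snp": ann.contains_snp,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations(
    mirna_bed: str | Path | None = None,
    utr_bed: str | Path | None = None,
    probe_tsv: str | Path | None = None,
) -> AnnotationSet:
    """Assemble an :class:`AnnotationSet` from BED + probe TSV files."""
    return AnnotationSet(
        mirna_intervals=read_bed(mirna_bed) if mirna_bed else {},
        utr_intervals=read_bed(utr_bed) if utr_bed else {},
        probes=read_probe_table(probe_tsv) if probe_tsv else {},
    )


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(records: Iterable[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write result records as a tab-separated table with a header row."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
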