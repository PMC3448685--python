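"""Core data types shared by every stage of the pipeline.

Coordinate convention: all intervals and SNP positions are held 0-based,
half-open (BED-style) in memory.  Anything user-facing that mirrors published
tables (probe spans, SNP positions) is 1-based inclusive and is converted at
the I/O boundary.  Strand is ignored throughout: SNP-in-region membership is
strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "SnpRecord",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "ProbeAnnotation",
    "CovariateTable",
    "AnnotationSet",
    "PROBE_QUALITY_VOCABULARY",
]

#: Closed vocabulary of probe re-annotation quality flags.  Only "perfect"
#: probes enter the analysis; the rest are carried through so selection
#: reports can account for them.
PROBE_QUALITY_VOCABULARY = frozenset(
    {"perfect", "good", "bad", "no_match", "unknown"}
)


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome label (non-empty; compared as a string).
    start, end : int
        0-based half-open bounds, ``start < end``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )

    @classmethod
    def from_1based(cls, chrom: str, start1: int, end1: int) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (as printed in tables)."""
        return cls(chrom, start1 - 1, end1)

    def to_1based(self) -> tuple[str, int, int]:
        """Return (chrom, start, end) as 1-based inclusive coordinates."""
        return (self.chrom, self.start + 1, self.end)

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 0-based position under half-open semantics."""
        return chrom == self.chrom and self.start <= pos < self.end

    def distance_to(self, chrom: str, pos: int) -> int | None:
        """Distance in bp from a 0-based position to the nearest interval edge.

        0 if the position lies inside; ``None`` on a different chromosome.
        """
        if chrom != self.chrom:
            return None
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - (self.end - 1)
        return 0


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP with dataset-determined allele orientation.

    ``minor`` is the rare allele in the dataset the record was derived from;
    dosages count copies of this allele.  Frequency ties are broken by taking
    the alphabetically-first allele as minor, so orientation is deterministic.
    """

    snp_id: str
    chrom: str
    pos: int  # 0-based
    major: str = "A"
    minor: str = "a"
    maf: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"{self.snp_id}: negative position")
        if np.isfinite(self.maf) and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: MAF {self.maf} outside [0, 0.5]")

    @property
    def pos1(self) -> int:
        """1-based position as printed in tables."""
        return self.pos + 1


class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix (0/1/2, NaN = missing)."""

    def __init__(
        self,
        dosages: pd.DataFrame,
        snps: Mapping[str, SnpRecord] | Iterable[SnpRecord] | None = None,
    ):
        if dosages.index.duplicated().any():
            raise ValueError("duplicated sample ids")
        if dosages.columns.duplicated().any():
            raise ValueError("duplicated SNP ids")
        vals = dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = dosages.columns[np.where(~ok)[1][0]]
            raise ValueError(f"dosage values outside {{0,1,2,missing}} at SNP {bad}")
        self.dosages = dosages.astype(float)
        if snps is None:
            snps = {}
        elif not isinstance(snps, Mapping):
            snps = {s.snp_id: s for s in snps}
        unknown = set(snps) - set(dosages.columns)
        if unknown:
            raise ValueError(f"SNP records without dosage columns: {sorted(unknown)}")
        self.snps: dict[str, SnpRecord] = dict(snps)

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_samples(self) -> int:
        return len(self.dosages.index)

    @property
    def n_snps(self) -> int:
        return len(self.dosages.columns)

    def dosage(self, snp_id: str) -> pd.Series:
        return self.dosages[snp_id]

    def record(self, snp_id: str) -> SnpRecord | None:
        return self.snps.get(snp_id)

    # -- per-SNP summaries ----------------------------------------------
    def call_rate(self, snp_id: str) -> float:
        g = self.dosages[snp_id]
        return float(g.notna().mean()) if len(g) else float("nan")

    def maf(self, snp_id: str) -> float:
        g = self.dosages[snp_id].dropna()
        if g.empty:
            return float("nan")
        f = float(g.mean() / 2.0)
        return min(f, 1.0 - f)

    def genotype_counts(self, snp_id: str) -> tuple[int, int, int]:
        """(n_hom_major, n_het, n_hom_minor) among called genotypes."""
        g = self.dosages[snp_id].dropna()
        return (int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        keep = [s for s in snp_ids if s in self.dosages.columns]
        return GenotypeMatrix(
            self.dosages[keep],
            {k: v for k, v in self.snps.items() if k in keep},
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[list(sample_ids)], self.snps)

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_snps} SNPs)"


class ExpressionMatrix:
    """Samples x probes matrix of normalized, log-scale intensities."""

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            raise ValueError("duplicated sample ids")
        if values.columns.duplicated().any():
            raise ValueError("duplicated probe ids")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        self.values = values.astype(float)

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return len(self.values.index)

    @property
    def n_probes(self) -> int:
        return len(self.values.columns)

    def probe(self, probe_id: str) -> pd.Series:
        return self.values[probe_id]

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_samples} samples x {self.n_probes} probes)"


@dataclass(frozen=True)
class ProbeAnnotation:
    """Annotation of one expression probe.

    ``quality`` is the re-annotation quality flag ("perfect" probes only are
    analysed); ``contains_snp`` flags probes whose genomic sequence harbours a
    SNP (excluded to avoid hybridisation artefacts masquerading as eQTLs).
    """

    probe_id: str
    gene: str
    interval: GenomicInterval
    quality: str = "perfect"
    contains_snp: bool = False


class CovariateTable:
    """Per-sample covariates: age (years), sex (0/1), optional status (0/1)."""

    REQUIRED = ("age", "sex")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"missing covariate columns: {missing}")
        if table.index.duplicated().any():
            raise ValueError("duplicated sample ids")
        self.table = table.astype(float)

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def has_status(self) -> bool:
        return "status" in self.table.columns

    def design_columns(self, include_status: bool = False) -> pd.DataFrame:
        cols = ["age", "sex"] + (["status"] if include_status and self.has_status else [])
        return self.table[cols]

    def __repr__(self) -> str:
        return f"CovariateTable({len(self.table)} samples, cols={list(self.table.columns)})"


@dataclass
class AnnotationSet:
    """Pri-miRNA intervals, 3'UTR intervals (pre-merged per gene), probes."""

    mirna_intervals: dict[str, GenomicInterval] = field(default_factory=dict)
    utr_intervals: dict[str, GenomicInterval] = field(default_factory=dict)
    probes: dict[str, ProbeAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # dict keys are unique by construction; validate probe id consistency
        for pid, ann in self.probes.items():
            if pid != ann.probe_id:
                raise ValueError(f"probe key {pid!r} != annotation id {ann.probe_id!r}")
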