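"""Selection of analysis units: miSNPs, 3'UTR SNPs, eligible probes.

A miSNP is a SNP falling inside an annotated pri-miRNA interval; a 3utrSNP
falls inside a gene's 3'UTR.  Either kind of SNP enters the analysis only
through a genotyped proxy in strong LD (possibly itself).  The selection
report reproduces the accounting used in published scans: a per-gene
histogram of 3utrSNP counts whose derived total can exceed the number of
distinct studied proxies, because one genotyped proxy may tag several
3utrSNPs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .datamodel import GenomicInterval, GenotypeMatrix, ProbeAnnotation
from .genetics import ProxyAssignment

logger = logging.getLogger(__name__)

__all__ = ["map_snps_to_regions", "filter_probes", "SelectionReport", "build_selection_report"]


def map_snps_to_regions(
    G: GenotypeMatrix,
    regions: dict[str, GenomicInterval],
) -> dict[str, list[str]]:
    """Assign each SNP to every region whose interval contains its position.

    Intervals are half-open; a SNP inside several overlapping regions is
    assigned to all of them.  SNPs without coordinate records, or outside
    every region, are simply absent from the result.
    """
    out: dict[str, list[str]] = {}
    for snp_id, rec in G.snps.items():
        hits = [
            name for name, iv in regions.items() if iv.contains(rec.chrom, rec.pos)
        ]
        if hits:
            out[snp_id] = sorted(hits)
    return out


def filter_probes(probes: dict[str, ProbeAnnotation]) -> dict[str, ProbeAnnotation]:
    """Keep probes of "perfect" re-annotation quality not harbouring a SNP."""
    return {
        pid: ann
        for pid, ann in probes.items()
        if ann.quality == "perfect" and not ann.contains_snp
    }


@dataclass
class SelectionReport:
    """Accounting of the selected analysis units.

    ``histogram`` maps (number of 3utrSNPs in a gene) -> (number of genes);
    its derived total sum_k k * count(k) counts tagged 3utrSNPs and can
    exceed ``n_3utrsnp`` (distinct studied proxies) when proxies are shared.
    """

    n_misnp: int = 0
    n_mirna_distinct: int = 0
    n_probes_marginal: int = 0
    n_genes_marginal: int = 0
    n_probes_interaction: int = 0
    n_genes_interaction: int = 0
    n_3utrsnp: int = 0
    histogram: dict[int, int] = field(default_factory=dict)

    @property
    def n_genes_with_utrsnp(self) -> int:
        return sum(self.histogram.values())

    @property
    def total_derivable_3utrsnps(self) -> int:
        """sum_k k * count(k): 3utrSNPs derivable from the per-gene histogram."""
        return sum(k * c for k, c in self.histogram.items())

    def validate(self) -> None:
        if self.n_genes_with_utrsnp != self.n_genes_interaction:
            raise ValueError(
                f"histogram covers {self.n_genes_with_utrsnp} genes, "
                f"expected {self.n_genes_interaction}"
            )
        if self.total_derivable_3utrsnps < self.n_3utrsnp:
            raise ValueError(
                "derived 3utrSNP total smaller than the number of studied proxies"
            )


def build_selection_report(
    misnp_assignments: dict[str, list[str]],
    utr_assignments: dict[str, list[str]],
    eligible_probes: dict[str, ProbeAnnotation],
    misnp_proxies: dict[str, ProxyAssignment],
    utr_proxies: dict[str, ProxyAssignment],
) -> SelectionReport:
    """Assemble the selection report from SNP-region maps and proxy maps.

    Parameters
    ----------
    misnp_assignments, utr_assignments : dict
        SNP id -> list of pri-miRNA names / gene names containing it.
    eligible_probes : dict
        Probes surviving :func:`filter_probes`.
    misnp_proxies, utr_proxies : dict
        Target SNP id -> proxy assignment for targets with a surviving
        proxy; targets absent from the map are dropped from the analysis.
    """
    misnps = sorted(set(misnp_assignments) & set(misnp_proxies))
    mirnas = {m for s in misnps for m in misnp_assignments[s]}

    utr_snps = sorted(set(utr_assignments) & set(utr_proxies))
    per_gene: Counter[str] = Counter()
    for snp in utr_snps:
        for gene in set(utr_assignments[snp]):
            per_gene[gene] += 1

    genes_marginal = {ann.gene for ann in eligible_probes.values()}
    genes_interaction = set(per_gene)
    probes_interaction = {
        pid for pid, ann in eligible_probes.items() if ann.gene in genes_interaction
    }
    # genes with a 3utrSNP but no eligible probe cannot be tested
    genes_interaction &= genes_marginal
    per_gene = Counter({g: c for g, c in per_gene.items() if g in genes_interaction})

    histogram = Counter(per_gene.values())
    report = SelectionReport(
        n_misnp=len(misnps),
        n_mirna_distinct=len(mirnas),
        n_probes_marginal=len(eligible_probes),
        n_genes_marginal=len(genes_marginal),
        n_probes_interaction=len(probes_interaction),
        n_genes_interaction=len(genes_interaction),
        n_3utrsnp=len(
            {utr_proxies[s].proxy_id for s in utr_snps if any(g in genes_interaction for g in utr_assignments[s])}
        ),
        histogram=dict(sorted(histogram.items())),
    )
    report.validate()
    return report
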