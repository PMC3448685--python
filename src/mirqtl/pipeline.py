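"""Orchestration of the two study workflows.

Discovery: select analysis units -> genotype QC -> marginal additive scan
(with Bonferroni threshold derived from executed-test counts) ->
Levene-weighted interaction scan.  Replication: re-test discovery hits in
an independent cohort under standard Bonferroni with disease status as an
extra covariate.  Every run emits a log of effective parameters, counts,
thresholds and per-stage skip reasons, so the number of executed tests is
auditable; re-running with identical config and inputs is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .association import AssociationScan, AssociationScanResults
from .datamodel import AnnotationSet, CovariateTable, ExpressionMatrix, GenotypeMatrix
from .genetics import ProxyAssignment, QcResult, QcThresholds, qc_filter_snps, select_proxy
from .interaction import (
    InteractionRecord,
    InteractionScan,
    InteractionScanResults,
    MiSnpUnit,
    UtrTestUnit,
    replicate_interactions,
)
from .io import write_results
from .selection import SelectionReport, build_selection_report, filter_probes, map_snps_to_regions

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "DiscoveryResult", "run_discovery", "run_replication"]


@dataclass
class RunConfig:
    """Effective parameters of one pipeline run."""

    qc: QcThresholds = field(default_factory=QcThresholds)
    window_bp: int = 1_000_000
    alpha: float = 0.05
    best_cis_p: float = 5.5e-5
    proxy_r2_min: float = 0.90
    weighting: str = "levene"  # "levene" | "none"
    levene_center: str = "mean"
    cohort_role: str = "discovery"  # "discovery" | "replication"
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.cohort_role not in ("discovery", "replication"):
            raise ValueError(f"cohort role must be discovery or replication, got {self.cohort_role!r}")
        for name in ("alpha", "best_cis_p", "proxy_r2_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


@dataclass
class DiscoveryResult:
    """Everything a discovery run produces."""

    qc: QcResult
    selection: SelectionReport
    misnp_assignments: dict[str, list[str]]
    utr_assignments: dict[str, list[str]]
    marginal: AssociationScanResults
    interaction: InteractionScanResults
    log: list[str] = field(default_factory=list)


def _check_sample_alignment(
    G: GenotypeMatrix, E: ExpressionMatrix, C: CovariateTable | None
) -> list[str]:
    sets = {"genotypes": set(G.sample_ids), "expression": set(E.sample_ids)}
    if C is not None:
        sets["covariates"] = set(C.sample_ids)
    union = set().union(*sets.values())
    inter = set.intersection(*sets.values())
    offenders = sorted(union - inter)
    if offenders:
        where = {
            s: [name for name, ids in sets.items() if s not in ids] for s in offenders
        }
        raise ValueError(
            "sample-id mismatch across inputs; missing: "
            + "; ".join(f"{s} (absent from {', '.join(w)})" for s, w in list(where.items())[:20])
        )
    return sorted(inter)


def run_discovery(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    covariates: CovariateTable | None,
    annotations: AnnotationSet,
    config: RunConfig | None = None,
) -> DiscoveryResult:
    """Execute the full discovery workflow on in-memory data.

    Stages: sample alignment check, QC, SNP-to-region selection, proxy
    resolution (a genotyped target is its own proxy; other targets fall
    back to the best in-sample LD proxy at r2 >= ``proxy_r2_min``), probe
    filtering, marginal scan, interaction scan, selection report.
    """
    if config is None:
        config = RunConfig()
    log: list[str] = [f"config: {config}"]
    _check_sample_alignment(genotypes, expression, covariates)

    qc = qc_filter_snps(genotypes, config.qc)
    G = qc.genotypes
    log.append(
        f"QC: kept {G.n_snps}/{genotypes.n_snps} SNPs; removed "
        + ", ".join(f"{k}={len(v)}" for k, v in qc.removed.items())
    )

    misnp_assignments = map_snps_to_regions(G, annotations.mirna_intervals)
    utr_assignments = map_snps_to_regions(G, annotations.utr_intervals)
    log.append(
        f"regions: {len(misnp_assignments)} miSNPs in pri-miRNAs, "
        f"{len(utr_assignments)} SNPs in 3'UTRs"
    )

    # genotyped targets are their own proxies (r2 = 1); target SNPs removed
    # by QC get a proxy among surviving SNPs when one reaches the threshold
    def resolve_proxies(targets: Sequence[str]) -> dict[str, ProxyAssignment]:
        out: dict[str, ProxyAssignment] = {}
        candidates = list(G.snp_ids)
        for t in targets:
            if t in G.snp_ids:
                out[t] = ProxyAssignment(t, t, 1.0)
                continue
            rec = genotypes.record(t)
            if rec is None or t not in genotypes.snp_ids:
                continue
            same_chrom = [
                c for c in candidates
                if (r := G.record(c)) is not None and r.chrom == rec.chrom
            ]
            prox = select_proxy(rec, same_chrom, genotypes, config.proxy_r2_min)
            if prox is not None:
                out[t] = prox
        return out

    misnp_proxies = resolve_proxies(sorted(misnp_assignments))
    utr_proxies = resolve_proxies(sorted(utr_assignments))

    eligible = filter_probes(annotations.probes)
    log.append(f"probes: {len(eligible)}/{len(annotations.probes)} eligible")

    selection = build_selection_report(
        misnp_assignments, utr_assignments, eligible, misnp_proxies, utr_proxies
    )
    log.append(
        f"selection: {selection.n_misnp} miSNPs / {selection.n_mirna_distinct} miRNAs; "
        f"{selection.n_3utrsnp} 3utrSNP proxies over {selection.n_genes_interaction} genes"
    )

    probe_intervals = {pid: ann.interval for pid, ann in annotations.probes.items()}
    mi_proxy_ids = sorted({misnp_proxies[t].proxy_id for t in misnp_proxies})
    marginal = AssociationScan(
        expression,
        G,
        covariates,
        probe_intervals=probe_intervals,
        snp_ids=mi_proxy_ids,
        probe_ids=sorted(eligible),
        window=config.window_bp,
        include_status=config.cohort_role == "replication",
    ).fit(alpha=config.alpha)
    log.append(
        f"marginal scan: {marginal.n_snps_tested} miSNP proxies x "
        f"{marginal.n_probes_tested} probes; Bonferroni threshold "
        f"{marginal.bonferroni_threshold:.3g}"
    )

    probes_by_gene: dict[str, list[str]] = {}
    for pid in sorted(eligible):
        probes_by_gene.setdefault(eligible[pid].gene, []).append(pid)
    units: list[UtrTestUnit] = []
    for utr_snp in sorted(utr_proxies):
        prox = utr_proxies[utr_snp]
        for gene in sorted(set(utr_assignments[utr_snp])):
            for pid in probes_by_gene.get(gene, []):
                units.append(
                    UtrTestUnit(gene=gene, probe_id=pid, utr_snp=utr_snp, utr_proxy=prox.proxy_id)
                )
    misnps = [
        MiSnpUnit(
            mi_snp=t,
            mi_proxy=misnp_proxies[t].proxy_id,
            mirna=";".join(misnp_assignments[t]),
        )
        for t in sorted(misnp_proxies)
    ]
    interaction = InteractionScan(
        expression,
        G,
        covariates,
        units,
        misnps,
        center=config.levene_center,
        weighting=config.weighting,
        include_status=config.cohort_role == "replication",
    ).fit(alpha=config.alpha)
    d = interaction.dimensions
    log.append(
        f"interaction scan: N={d.n_tests} executed over {d.n_utr} units x "
        f"{d.n_misnp} miSNPs ({len(interaction.skipped)} skipped); "
        f"threshold {interaction.threshold:.3g}; "
        f"{len(interaction.significant())} significant"
    )

    result = DiscoveryResult(
        qc=qc,
        selection=selection,
        misnp_assignments=misnp_assignments,
        utr_assignments=utr_assignments,
        marginal=marginal,
        interaction=interaction,
        log=log,
    )
    if config.out_dir is not None:
        _write_discovery(result, Path(config.out_dir))
    return result


def _write_discovery(result: DiscoveryResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_results(result.marginal.to_frame(), out_dir / "marginal_scan.tsv")
    write_results(result.interaction.to_frame(), out_dir / "interaction_scan.tsv")
    # two-row layout: k (3utrSNPs per gene) across, gene counts beneath
    hist = pd.DataFrame(
        [list(result.selection.histogram.values())],
        columns=[str(k) for k in result.selection.histogram],
        index=pd.Index(["n_genes"], name="n_3utrsnps_per_gene"),
    )
    hist.to_csv(out_dir / "selection_histogram.tsv", sep="\t")
    summary = pd.DataFrame([{
        k: getattr(result.selection, k)
        for k in (
            "n_misnp", "n_mirna_distinct", "n_probes_marginal", "n_genes_marginal",
            "n_probes_interaction", "n_genes_interaction", "n_3utrsnp",
        )
    }])
    write_results(summary, out_dir / "selection_report.tsv")
    (out_dir / "run.log").write_text("\n".join(result.log) + "\n")


def run_replication(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    covariates: CovariateTable | None,
    hits: Sequence[InteractionRecord],
    config: RunConfig | None = None,
    proxy_map: dict[str, str] | None = None,
    probe_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Replication workflow: re-test discovery hits under standard
    Bonferroni (alpha / number of replicable hits), adjusting additionally
    for disease status when present."""
    if config is None:
        config = RunConfig(cohort_role="replication")
    _check_sample_alignment(genotypes, expression, covariates)
    qc = qc_filter_snps(genotypes, config.qc)
    df = replicate_interactions(
        hits,
        expression,
        qc.genotypes,
        covariates,
        proxy_map=proxy_map,
        probe_map=probe_map,
        alpha=config.alpha,
    )
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_results(df, out_dir / "replication.tsv")
    return df
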