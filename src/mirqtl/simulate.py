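"""Synthetic genotype/expression scenario generator with known ground truth.

The generator emulates every statistical structure the analysis assumes:
Hardy-Weinberg genotypes at specified MAFs, two-locus LD pairs drawn from
specified haplotype frequencies, expression built from additive SNP
effects, SNP x SNP interaction effects, mediator chains (SNP -> mediator
gene -> downstream genes), genotype-dependent residual variance (to
exercise the Levene prioritization), and age/sex/status covariate effects.
A single global seed expands into per-component substreams through
``numpy.random.SeedSequence`` spawning, so bundles are bit-reproducible.

What it does not emulate: realistic genome-wide LD maps, array-level probe
noise, or population structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AnnotationSet,
    CovariateTable,
    ExpressionMatrix,
    GenomicInterval,
    GenotypeMatrix,
    ProbeAnnotation,
    SnpRecord,
)

__all__ = [
    "SnpSpec",
    "LdPairSpec",
    "ProbeSpec",
    "AdditiveEffect",
    "InteractionEffect",
    "MediatorChain",
    "VariancePlan",
    "ScenarioConfig",
    "ScenarioBundle",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_expression",
    "simulate_bundle",
    "make_paper_like_scenario",
    "make_global_null_scenario",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpSpec:
    """An independent HWE SNP (unless listed in an LD pair)."""

    snp_id: str
    chrom: str
    pos: int  # 0-based
    maf: float

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: MAF {self.maf} outside (0, 0.5]")


@dataclass(frozen=True)
class LdPairSpec:
    """Two SNPs drawn jointly from specified haplotype frequencies.

    ``freqs`` is (f_AB, f_Ab, f_aB, f_ab): A/B major alleles, a/b minor
    (dosage-counted) alleles.
    """

    snp1: str
    snp2: str
    freqs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"invalid haplotype frequencies for ({self.snp1}, {self.snp2})")


@dataclass(frozen=True)
class ProbeSpec:
    probe_id: str
    gene: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    quality: str = "perfect"
    contains_snp: bool = False
    baseline: float = 8.0  # typical normalized log-intensity level


@dataclass(frozen=True)
class AdditiveEffect:
    snp_id: str
    probe_id: str
    beta: float


@dataclass(frozen=True)
class InteractionEffect:
    utr_snp: str
    mi_snp: str
    probe_id: str
    beta: float


@dataclass(frozen=True)
class MediatorChain:
    """snp -> mediator probe -> downstream probe (sequential generation)."""

    snp_id: str
    mediator_probe: str
    target_probe: str
    beta_snp: float      # effect of the SNP on the mediator
    beta_mediator: float  # effect of mediator expression on the target


@dataclass(frozen=True)
class VariancePlan:
    """Residual sd of a probe per genotype class of a SNP."""

    snp_id: str
    probe_id: str
    sd_by_genotype: tuple[float, float, float]


@dataclass
class ScenarioConfig:
    """Full ground-truth parameterization of one synthetic cohort.

    Covariate effects apply to every probe: expression gains
    ``age_slope * (age - 55)``, ``sex_offset * sex`` and (when ``with_status``)
    ``status_offset * status``.  ``noise_sd`` is the homoskedastic residual
    sd wherever no variance plan applies.
    """

    n_samples: int
    snps: list[SnpSpec] = field(default_factory=list)
    ld_pairs: list[LdPairSpec] = field(default_factory=list)
    probes: list[ProbeSpec] = field(default_factory=list)
    additive: list[AdditiveEffect] = field(default_factory=list)
    interactions: list[InteractionEffect] = field(default_factory=list)
    mediations: list[MediatorChain] = field(default_factory=list)
    variance_plans: list[VariancePlan] = field(default_factory=list)
    mirna_of_snp: dict[str, str] = field(default_factory=dict)  # miSNP -> miRNA name
    age_slope: float = 0.005
    sex_offset: float = 0.05
    status_offset: float = 0.05
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    with_status: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        snp_ids = {s.snp_id for s in self.snps}
        probe_ids = {p.probe_id for p in self.probes}
        if len(snp_ids) != len(self.snps):
            raise ValueError("duplicated SNP ids in config")
        if len(probe_ids) != len(self.probes):
            raise ValueError("duplicated probe ids in config")
        for pair in self.ld_pairs:
            for s in (pair.snp1, pair.snp2):
                if s not in snp_ids:
                    raise ValueError(f"LD pair references unknown SNP {s}")
        for eff in self.additive:
            if eff.snp_id not in snp_ids or eff.probe_id not in probe_ids:
                raise ValueError(f"additive effect references unknown ids: {eff}")
        for eff in self.interactions:
            if {eff.utr_snp, eff.mi_snp} - snp_ids or eff.probe_id not in probe_ids:
                raise ValueError(f"interaction effect references unknown ids: {eff}")
        for ch in self.mediations:
            if ch.snp_id not in snp_ids or {ch.mediator_probe, ch.target_probe} - probe_ids:
                raise ValueError(f"mediator chain references unknown ids: {ch}")
        for vp in self.variance_plans:
            if vp.snp_id not in snp_ids or vp.probe_id not in probe_ids:
                raise ValueError(f"variance plan references unknown ids: {vp}")


@dataclass
class ScenarioBundle:
    """Generated data plus the ground-truth ledger needed to score recovery."""

    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    covariates: CovariateTable
    annotations: AnnotationSet
    config: ScenarioConfig
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-component substreams from one global seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genotypes(config: ScenarioConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw genotypes: HWE binomials for independent SNPs, haplotype pairs
    for LD-linked SNPs, optional missingness."""
    if rng is None:
        rng = _substreams(config.seed, 3)[0]
    n = config.n_samples
    sample_ids = pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id")
    paired = {s for p in config.ld_pairs for s in (p.snp1, p.snp2)}
    cols: dict[str, np.ndarray] = {}
    for spec in config.snps:
        if spec.snp_id in paired:
            continue
        cols[spec.snp_id] = rng.binomial(2, spec.maf, size=n).astype(float)
    for pair in config.ld_pairs:
        f = np.asarray(pair.freqs, dtype=float)
        haps = rng.choice(4, size=(n, 2), p=f)
        # minor-allele dosage at locus 1: haplotypes aB (2) and ab (3)
        cols[pair.snp1] = np.isin(haps, (2, 3)).sum(axis=1).astype(float)
        # at locus 2: haplotypes Ab (1) and ab (3)
        cols[pair.snp2] = np.isin(haps, (1, 3)).sum(axis=1).astype(float)
    if config.missing_rate > 0:
        for snp_id in cols:
            miss = rng.random(n) < config.missing_rate
            cols[snp_id][miss] = np.nan
    records = {}
    for spec in config.snps:
        g = cols[spec.snp_id]
        called = g[np.isfinite(g)]
        maf_obs = float(called.mean() / 2.0) if called.size else float("nan")
        records[spec.snp_id] = SnpRecord(
            snp_id=spec.snp_id, chrom=spec.chrom, pos=spec.pos,
            major="A", minor="a", maf=min(maf_obs, 1.0 - maf_obs),
        )
    df = pd.DataFrame({s.snp_id: cols[s.snp_id] for s in config.snps}, index=sample_ids)
    return GenotypeMatrix(df, records)


def simulate_covariates(config: ScenarioConfig, rng: np.random.Generator | None = None) -> CovariateTable:
    """Age ~ Uniform(35, 74), sex ~ Bernoulli(0.5), status ~ Bernoulli(0.48)."""
    if rng is None:
        rng = _substreams(config.seed, 3)[1]
    n = config.n_samples
    sample_ids = pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id")
    data = {
        "age": rng.uniform(35.0, 74.0, size=n),
        "sex": rng.integers(0, 2, size=n).astype(float),
    }
    if config.with_status:
        data["status"] = (rng.random(n) < 0.48).astype(float)
    return CovariateTable(pd.DataFrame(data, index=sample_ids))


def simulate_expression(
    G: GenotypeMatrix,
    covariates: CovariateTable,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Build expression from the effect plan.

    y = baseline + covariate terms + sum(additive beta * g)
      + sum(interaction beta * g1 * g2) + mediator contributions
      + noise with per-sample sd from the variance plan (homoskedastic
      ``noise_sd`` by default).  Mediator chains are generated sequentially
    (mediator first, then its targets); cyclic chains are rejected.
    """
    if rng is None:
        rng = _substreams(config.seed, 3)[2]
    n = config.n_samples
    age = covariates.table["age"].to_numpy()
    sex = covariates.table["sex"].to_numpy()
    status = covariates.table["status"].to_numpy() if covariates.has_status else None

    # topological order of probes under mediator edges
    deps: dict[str, set[str]] = {p.probe_id: set() for p in config.probes}
    for ch in config.mediations:
        deps[ch.target_probe].add(ch.mediator_probe)
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(pid: str) -> None:
        if state.get(pid) == 1:
            raise ValueError("cyclic mediator chain")
        if state.get(pid) == 2:
            return
        state[pid] = 1
        for dep in deps[pid]:
            visit(dep)
        state[pid] = 2
        order.append(pid)

    for p in config.probes:
        visit(p.probe_id)

    spec_by_id = {p.probe_id: p for p in config.probes}
    add_by_probe: dict[str, list[AdditiveEffect]] = {}
    for eff in config.additive:
        add_by_probe.setdefault(eff.probe_id, []).append(eff)
    int_by_probe: dict[str, list[InteractionEffect]] = {}
    for eff in config.interactions:
        int_by_probe.setdefault(eff.probe_id, []).append(eff)
    med_by_target: dict[str, list[MediatorChain]] = {}
    for ch in config.mediations:
        med_by_target.setdefault(ch.target_probe, []).append(ch)
        # the SNP->mediator leg is an additive effect on the mediator
        add_by_probe.setdefault(ch.mediator_probe, []).append(
            AdditiveEffect(ch.snp_id, ch.mediator_probe, ch.beta_snp)
        )
    var_by_probe: dict[str, list[VariancePlan]] = {}
    for vp in config.variance_plans:
        var_by_probe.setdefault(vp.probe_id, []).append(vp)

    def dosage(snp_id: str) -> np.ndarray:
        g = G.dosages[snp_id].to_numpy()
        return np.nan_to_num(g, nan=float(np.nanmean(g)))  # mean-impute for generation

    values: dict[str, np.ndarray] = {}
    for pid in order:
        spec = spec_by_id[pid]
        y = np.full(n, spec.baseline)
        y += config.age_slope * (age - 55.0) + config.sex_offset * sex
        if status is not None:
            y += config.status_offset * status
        for eff in add_by_probe.get(pid, []):
            y += eff.beta * dosage(eff.snp_id)
        for eff in int_by_probe.get(pid, []):
            y += eff.beta * dosage(eff.utr_snp) * dosage(eff.mi_snp)
        for ch in med_by_target.get(pid, []):
            y += ch.beta_mediator * values[ch.mediator_probe]
        sd = np.full(n, config.noise_sd)
        for vp in var_by_probe.get(pid, []):
            g = dosage(vp.snp_id)
            for geno in (0, 1, 2):
                sd[np.rint(g).astype(int) == geno] = vp.sd_by_genotype[geno]
        y += rng.normal(0.0, sd)
        values[pid] = y

    df = pd.DataFrame(
        {p.probe_id: values[p.probe_id] for p in config.probes},
        index=covariates.sample_ids,
    )
    return ExpressionMatrix(df)


def _annotations_from_config(
    config: ScenarioConfig,
    mirna_intervals: dict[str, GenomicInterval] | None = None,
    utr_intervals: dict[str, GenomicInterval] | None = None,
) -> AnnotationSet:
    probes = {
        p.probe_id: ProbeAnnotation(
            probe_id=p.probe_id,
            gene=p.gene,
            interval=GenomicInterval(p.chrom, p.start, p.end),
            quality=p.quality,
            contains_snp=p.contains_snp,
        )
        for p in config.probes
    }
    return AnnotationSet(
        mirna_intervals=dict(mirna_intervals or {}),
        utr_intervals=dict(utr_intervals or {}),
        probes=probes,
    )


def simulate_bundle(
    config: ScenarioConfig,
    mirna_intervals: dict[str, GenomicInterval] | None = None,
    utr_intervals: dict[str, GenomicInterval] | None = None,
    truth: dict | None = None,
) -> ScenarioBundle:
    """Generate a full bundle (genotypes, expression, covariates,
    annotations, ground truth) from a config, reproducibly for its seed."""
    g_rng, c_rng, e_rng = _substreams(config.seed, 3)
    G = simulate_genotypes(config, g_rng)
    C = simulate_covariates(config, c_rng)
    E = simulate_expression(G, C, config, e_rng)
    base_truth = {
        "additive": [asdict(e) for e in config.additive],
        "interactions": [asdict(e) for e in config.interactions],
        "mediations": [asdict(e) for e in config.mediations],
        "variance_plans": [asdict(e) for e in config.variance_plans],
    }
    base_truth.update(truth or {})
    return ScenarioBundle(
        genotypes=G,
        expression=E,
        covariates=C,
        annotations=_annotations_from_config(config, mirna_intervals, utr_intervals),
        config=config,
        truth=base_truth,
    )


# ---------------------------------------------------------------------------
# canned scenarios
# ---------------------------------------------------------------------------

#: Per-gene 3utrSNP count profile for the miniature scenario: a decreasing
#: histogram (most genes carry one 3'UTR SNP, few carry many), echoing the
#:  shape observed in genome-wide selections.
_UTR_COUNT_PROFILE = [1] * 34 + [2] * 14 + [3] * 6 + [4] * 3 + [5] * 2 + [8]


def make_paper_like_scenario(
    n_samples: int = 800,
    n_misnp: int = 30,
    seed: int = 0,
    n_interactions: int = 2,
    beta_interaction: float = 0.5,
) -> ScenarioBundle:
    """A miniature of a genome-wide scan with every structure planted.

    Defaults: 30 miSNPs (one per pri-miRNA), 60 genes carrying ~100 3utrSNPs
    with a decreasing per-gene histogram, ~200 probes (including
    non-"perfect" and SNP-harbouring probes that the filters must drop),
    2 planted interactions (beta_int = 0.5), one mediation chain
    (cis mediator gene driving a trans gene), variance heterogeneity at two
    3utrSNP units, and LD proxy pairs at r^2 >= 0.9 for a subset of targets.
    The ground-truth ledger records everything needed to score recovery.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA11CE)))
    snps: list[SnpSpec] = []
    ld_pairs: list[LdPairSpec] = []
    probes: list[ProbeSpec] = []
    mirna_intervals: dict[str, GenomicInterval] = {}
    utr_intervals: dict[str, GenomicInterval] = {}
    mirna_of_snp: dict[str, str] = {}

    # --- miSNPs, one per pri-miRNA interval, spread over chromosomes ----
    mi_snp_ids = []
    for i in range(n_misnp):
        chrom = str(1 + i % 22)
        pos = 1_000_000 + 50_000 * i
        snp_id = f"rs_mi{i:03d}"
        maf = float(rng.uniform(0.1, 0.5))
        snps.append(SnpSpec(snp_id, chrom, pos, maf))
        mirna = f"mir-{i:03d}"
        mirna_intervals[mirna] = GenomicInterval(chrom, pos - 40, pos + 40)
        mirna_of_snp[snp_id] = mirna
        mi_snp_ids.append(snp_id)

    # --- genes, 3'UTR SNPs and probes ------------------------------------
    counts = list(_UTR_COUNT_PROFILE)
    utr_snps_of_gene: dict[str, list[str]] = {}
    probe_of_gene: dict[str, str] = {}
    k = 0
    for gi, n_utr in enumerate(counts):
        gene = f"GENE{gi:03d}"
        chrom = str(1 + gi % 22)
        gstart = 5_000_000 + 200_000 * gi
        utr = GenomicInterval(chrom, gstart + 9_000, gstart + 10_000)
        utr_intervals[gene] = utr
        ids = []
        for j in range(n_utr):
            snp_id = f"rs_utr{k:04d}"
            k += 1
            snps.append(
                SnpSpec(snp_id, chrom, utr.start + 10 + 37 * j, float(rng.uniform(0.1, 0.5)))
            )
            ids.append(snp_id)
        utr_snps_of_gene[gene] = ids
        probe_id = f"PRB_{gene}"
        probes.append(ProbeSpec(probe_id, gene, chrom, gstart, gstart + 9_000))
        probe_of_gene[gene] = probe_id

    # genes without 3'UTR SNPs (marginal-only) and filter-exercising probes
    n_extra = 120
    for gi in range(len(counts), len(counts) + n_extra):
        gene = f"GENE{gi:03d}"
        chrom = str(1 + gi % 22)
        gstart = 5_000_000 + 200_000 * gi
        quality = "perfect"
        contains_snp = False
        if gi % 6 == 0:
            quality = "good"        # dropped by the quality filter
        elif gi % 6 == 1:
            contains_snp = True     # dropped by the SNP-in-probe filter
        probes.append(
            ProbeSpec(f"PRB_{gene}", gene, chrom, gstart, gstart + 9_000,
                      quality=quality, contains_snp=contains_snp)
        )

    # --- LD proxy pairs for a subset of targets --------------------------
    # an ungenotyped target tagged by a genotyped proxy at r^2 ~ 0.93
    ungenotyped_targets: dict[str, str] = {}  # target -> its genotyped proxy
    proxy_sources = [g for g, ids in utr_snps_of_gene.items() if len(ids) >= 2][:4]
    for gene in proxy_sources:
        target = utr_snps_of_gene[gene][0]
        proxy_id = f"{target}_proxy"
        t_spec = next(s for s in snps if s.snp_id == target)
        # proxy sits just outside the 3'UTR so it is a tag, not a target
        snps.append(SnpSpec(proxy_id, t_spec.chrom, t_spec.pos + 2_000, t_spec.maf))
        q = t_spec.maf
        eps = 0.015 * q  # small haplotype leakage keeps r^2 just above 0.9
        freqs = (1 - q - eps, eps, eps, q - eps)
        ld_pairs.append(LdPairSpec(target, proxy_id, freqs))
        ungenotyped_targets[target] = proxy_id

    # --- effect plan ------------------------------------------------------
    interactions: list[InteractionEffect] = []
    genes_cycle = [g for g in utr_snps_of_gene if g not in proxy_sources]
    for i in range(n_interactions):
        gene = genes_cycle[3 * i + 1]
        interactions.append(
            InteractionEffect(
                utr_snp=utr_snps_of_gene[gene][0],
                mi_snp=mi_snp_ids[i],
                probe_id=probe_of_gene[gene],
                beta=beta_interaction,
            )
        )

    # mediation chain patterned on a cis mediator driving a trans gene:
    # miSNP -> (cis) mediator gene expression -> (trans) downstream gene
    med_gene = genes_cycle[0]
    down_gene = next(
        g for g in genes_cycle
        if probe_of_gene[g] not in {e.probe_id for e in interactions} and g != med_gene
    )
    mediations = [
        MediatorChain(
            snp_id=mi_snp_ids[-1],
            mediator_probe=probe_of_gene[med_gene],
            target_probe=probe_of_gene[down_gene],
            beta_snp=0.6,
            beta_mediator=0.5,
        )
    ]

    # genotype-dependent variance at two 3utrSNP units
    het_genes = [g for g in genes_cycle if g not in (med_gene, down_gene)][-2:]
    variance_plans = [
        VariancePlan(
            snp_id=utr_snps_of_gene[g][0],
            probe_id=probe_of_gene[g],
            sd_by_genotype=(1.0, 1.5, 2.0),
        )
        for g in het_genes
    ]

    config = ScenarioConfig(
        n_samples=n_samples,
        snps=snps,
        ld_pairs=ld_pairs,
        probes=probes,
        additive=[],
        interactions=interactions,
        mediations=mediations,
        variance_plans=variance_plans,
        mirna_of_snp=mirna_of_snp,
        seed=seed,
    )

    # expected selection accounting: per-gene distinct 3utrSNP counts
    planted_hist: dict[int, int] = {}
    for gene, ids in utr_snps_of_gene.items():
        planted_hist[len(ids)] = planted_hist.get(len(ids), 0) + 1

    truth = {
        "planted_histogram": planted_hist,
        "utr_snps_of_gene": utr_snps_of_gene,
        "probe_of_gene": probe_of_gene,
        "mi_snp_ids": mi_snp_ids,
        "ungenotyped_targets": ungenotyped_targets,
    }
    return simulate_bundle(config, mirna_intervals, utr_intervals, truth)


def make_global_null_scenario(
    n_samples: int = 300,
    n_units: int = 10,
    n_misnp: int = 20,
    het_fraction: float = 0.2,
    sd_by_genotype: tuple[float, float, float] = (1.0, 1.5, 2.0),
    seed: int = 0,
) -> ScenarioBundle:
    """A global-null interaction-scan scenario for FWER calibration.

    No interaction effects are planted; a fraction of the 3utrSNP units
    carry genotype-dependent residual variance so the Levene weights are
    genuinely non-uniform.  Used to check that the weighted procedure keeps
    family-wise error at or below the nominal level.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x9011)))
    snps: list[SnpSpec] = []
    probes: list[ProbeSpec] = []
    mi_ids = []
    for i in range(n_misnp):
        snp_id = f"mi{i:03d}"
        snps.append(SnpSpec(snp_id, str(1 + i % 22), 1_000_000 + 1000 * i,
                            float(rng.uniform(0.1, 0.5))))
        mi_ids.append(snp_id)
    variance_plans = []
    n_het = int(round(het_fraction * n_units))
    for u in range(n_units):
        snp_id = f"utr{u:03d}"
        probe_id = f"PRB{u:03d}"
        chrom = str(1 + u % 22)
        snps.append(SnpSpec(snp_id, chrom, 9_000_000 + 1000 * u,
                            float(rng.uniform(0.1, 0.5))))
        probes.append(ProbeSpec(probe_id, f"G{u:03d}", chrom,
                                9_000_000 + 1000 * u, 9_000_000 + 1000 * u + 500))
        if u < n_het:
            variance_plans.append(VariancePlan(snp_id, probe_id, sd_by_genotype))
    config = ScenarioConfig(
        n_samples=n_samples,
        snps=snps,
        probes=probes,
        variance_plans=variance_plans,
        seed=seed,
    )
    truth = {
        "utr_units": [(f"utr{u:03d}", f"PRB{u:03d}", f"G{u:03d}") for u in range(n_units)],
        "mi_snp_ids": mi_ids,
    }
    return simulate_bundle(config, truth=truth)


def write_bundle(bundle: ScenarioBundle, out_dir) -> None:
    """Write a bundle to disk: VCF + dosage/expression/covariate TSVs,
    BED annotation files, probe table, and the ground-truth ledger."""
    import json
    from pathlib import Path

    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_vcf(bundle.genotypes, out / "genotypes.vcf")
    _io.write_dosage_tsv(bundle.genotypes, out / "dosages.tsv")
    _io.write_snp_table(bundle.genotypes, out / "snps.tsv")
    _io.write_expression(bundle.expression, out / "expression.tsv")
    _io.write_covariates(bundle.covariates, out / "covariates.tsv")
    _io.write_bed(bundle.annotations.mirna_intervals, out / "mirna.bed")
    _io.write_bed(bundle.annotations.utr_intervals, out / "utr.bed")
    _io.write_probe_table(bundle.annotations.probes, out / "probes.tsv")

    rows = []
    for kind in ("additive", "interactions", "mediations", "variance_plans"):
        for entry in bundle.truth.get(kind, []):
            rows.append({"kind": kind, **{k: str(v) for k, v in entry.items()}})
    pd.DataFrame(rows).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    extras = {k: v for k, v in bundle.truth.items()
              if k not in ("additive", "interactions", "mediations", "variance_plans")}
    (out / "ground_truth.json").write_text(json.dumps(extras, indent=1, default=str))
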