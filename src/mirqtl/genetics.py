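"""Genotype QC, two-locus haplotype EM, LD statistics and proxy selection.

The two-locus haplotype frequency estimator is a deterministic EM on unphased
dosage pairs: only double heterozygotes carry phase ambiguity, so the
likelihood has a single free parameter and the EM is initialised at linkage
equilibrium (product of allele frequencies) with no restarts.  LD statistics
(D, D', r^2) are derived from the EM haplotype frequencies, matching how
reference-panel tools report pairwise LD, rather than from genotype
correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .datamodel import GenotypeMatrix, SnpRecord

logger = logging.getLogger(__name__)

__all__ = [
    "QcThresholds",
    "QcResult",
    "qc_filter_snps",
    "hwe_exact_test",
    "HaplotypeFreqs",
    "em_haplotype_frequencies",
    "LdStats",
    "ld_from_haplotypes",
    "ld_between_snps",
    "ProxyAssignment",
    "select_proxy",
]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcThresholds:
    """SNP-level QC thresholds.

    Defaults are the discovery-cohort criteria (MAF > 0.01, call rate > 0.98,
    HWE exact p > 1e-4); a replication-style setting would use call rate >
    0.95 and HWE p > 1e-5.
    """

    maf_min: float = 0.01
    call_rate_min: float = 0.98
    hwe_p_min: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_p_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcResult:
    """Filtered genotypes plus an accounting of per-filter removals."""

    genotypes: GenotypeMatrix
    removed: dict[str, list[str]] = field(
        default_factory=lambda: {"maf": [], "call_rate": [], "hwe": []}
    )

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, enumerates every possible
    heterozygote count (same parity as the minor-allele count) and sums the
    probabilities of all configurations no more probable than the observed
    one.  Returns 1.0 for degenerate cases (no called genotypes or a
    monomorphic SNP).
    """
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)  # orient to the rarer allele
    if n_minor == 0:
        return 1.0

    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(het = h | allele counts); constants cancel in the normalisation
    rare_hom = (n_minor - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = n_het
    p_obs = p[hets == obs][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def qc_filter_snps(G: GenotypeMatrix, t: QcThresholds | None = None) -> QcResult:
    """Filter SNPs on MAF, then call rate, then HWE exact test.

    A SNP is retained iff MAF > ``t.maf_min`` AND call rate >
    ``t.call_rate_min`` AND HWE exact p > ``t.hwe_p_min``; each SNP is
    attributed to the first filter it fails.  SNPs with zero called
    genotypes are removed (logged) at the MAF step.
    """
    if t is None:
        t = QcThresholds()
    removed: dict[str, list[str]] = {"maf": [], "call_rate": [], "hwe": []}
    keep: list[str] = []
    for snp_id in G.snp_ids:
        maf = G.maf(snp_id)
        if not (maf > t.maf_min):  # NaN (zero called) also fails here
            if np.isnan(maf):
                logger.warning("SNP %s has zero called genotypes; removed", snp_id)
            removed["maf"].append(snp_id)
            continue
        if not (G.call_rate(snp_id) > t.call_rate_min):
            removed["call_rate"].append(snp_id)
            continue
        if not (hwe_exact_test(*G.genotype_counts(snp_id)) > t.hwe_p_min):
            removed["hwe"].append(snp_id)
            continue
        keep.append(snp_id)
    return QcResult(genotypes=G.subset_snps(keep), removed=removed)


# ---------------------------------------------------------------------------
# two-locus haplotype EM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeFreqs:
    """Frequencies of the four ordered two-locus haplotypes.

    Labels: ``A``/``B`` are the dosage-reference (major) alleles at the
    first/second locus, ``a``/``b`` the minor (dosage-counted) alleles;
    order is (AB, Ab, aB, ab).
    """

    f_AB: float
    f_Ab: float
    f_aB: float
    f_ab: float
    degenerate: bool = False  # a locus was monomorphic in the fitting data

    def __post_init__(self) -> None:
        f = self.as_array()
        if (f < -1e-12).any():
            raise ValueError("negative haplotype frequency")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {f.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.f_AB, self.f_Ab, self.f_aB, self.f_ab], dtype=float)

    @property
    def p_A(self) -> float:
        """Frequency of the major allele at locus 1."""
        return self.f_AB + self.f_Ab

    @property
    def p_B(self) -> float:
        """Frequency of the major allele at locus 2."""
        return self.f_AB + self.f_aB


_HAP_PAIRS = {
    # genotype pair (dosage1, dosage2) -> haplotype index pair, unambiguous cases
    (0, 0): (0, 0), (0, 1): (0, 1), (0, 2): (1, 1),
    (1, 0): (0, 2), (1, 2): (1, 3),
    (2, 0): (2, 2), (2, 1): (2, 3), (2, 2): (3, 3),
}


def _genotype_pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 table of counts over pair-complete samples."""
    mask = ~(np.isnan(g1) | np.isnan(g2))
    a = g1[mask].astype(int)
    b = g2[mask].astype(int)
    counts = np.zeros((3, 3), dtype=float)
    np.add.at(counts, (a, b), 1.0)
    return counts


def _loglik(counts: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of the genotype-pair table under freqs f."""
    probs = np.zeros((3, 3))
    for (d1, d2), (i, j) in _HAP_PAIRS.items():
        probs[d1, d2] = (1 if i == j else 2) * f[i] * f[j]
    probs[1, 1] = 2 * f[0] * f[3] + 2 * f[1] * f[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(probs), 0.0)
    return float(ll.sum())


def em_haplotype_frequencies(
    g1: np.ndarray,
    g2: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> HaplotypeFreqs:
    """Maximum-likelihood two-locus haplotype frequencies by EM.

    Operates on paired dosage vectors (0/1/2, NaN missing); samples missing
    either genotype are dropped.  Only double heterozygotes are phase
    ambiguous.  Converged when the largest frequency change is below ``tol``
    or after ``max_iter`` iterations.  A monomorphic locus yields degenerate
    frequencies flagged via :attr:`HaplotypeFreqs.degenerate`.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    counts = _genotype_pair_counts(g1, g2)
    n = counts.sum()
    if n < 2:
        raise ValueError(f"need >=2 pair-complete samples, have {int(n)}")

    # allele frequencies of the minor (dosage-counted) alleles
    q1 = (counts * np.arange(3)[:, None]).sum() / (2 * n)
    q2 = (counts * np.arange(3)[None, :]).sum() / (2 * n)
    if q1 in (0.0, 1.0) or q2 in (0.0, 1.0):
        logger.warning("monomorphic locus in EM input; degenerate frequencies")
        f = np.array([(1 - q1) * (1 - q2), (1 - q1) * q2, q1 * (1 - q2), q1 * q2])
        return HaplotypeFreqs(*f, degenerate=True)

    # initialise at linkage equilibrium
    f = np.array([(1 - q1) * (1 - q2), (1 - q1) * q2, q1 * (1 - q2), q1 * q2])
    n_dh = counts[1, 1]
    for _ in range(max_iter):
        hap = np.zeros(4)
        for (d1, d2), (i, j) in _HAP_PAIRS.items():
            hap[i] += counts[d1, d2]
            hap[j] += counts[d1, d2]
        if n_dh > 0:
            denom = f[0] * f[3] + f[1] * f[2]
            w = 0.5 if denom == 0 else f[0] * f[3] / denom
            hap[[0, 3]] += n_dh * w
            hap[[1, 2]] += n_dh * (1 - w)
        f_new = hap / (2 * n)
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    return HaplotypeFreqs(*f)


# ---------------------------------------------------------------------------
# LD statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LdStats:
    """Pairwise LD derived from haplotype frequencies.

    ``D`` is the haplotype-frequency covariance, ``D_prime = |D| / D_max``
    in [0, 1], ``r2 = D^2 / (p_A p_a p_B p_b)`` in [0, 1].
    """

    D: float
    D_prime: float
    r2: float


def ld_from_haplotypes(h: HaplotypeFreqs) -> LdStats:
    """Compute D, D' and r^2 from two-locus haplotype frequencies."""
    p_A, p_B = h.p_A, h.p_B
    p_a, p_b = 1.0 - p_A, 1.0 - p_B
    if min(p_A, p_a, p_B, p_b) <= 0.0:
        raise ValueError("LD undefined: a locus is monomorphic")
    D = h.f_AB - p_A * p_B
    if D > 0:
        d_max = min(p_A * p_b, p_a * p_B)
    else:
        d_max = min(p_A * p_B, p_a * p_b)
    d_prime = 0.0 if D == 0 else abs(D) / d_max
    r2 = D * D / (p_A * p_a * p_B * p_b)
    return LdStats(D=D, D_prime=min(d_prime, 1.0), r2=min(r2, 1.0))


def ld_between_snps(G: GenotypeMatrix, snp1: str, snp2: str) -> LdStats:
    """EM-based pairwise LD between two SNP columns of a genotype matrix."""
    h = em_haplotype_frequencies(
        G.dosages[snp1].to_numpy(), G.dosages[snp2].to_numpy()
    )
    return ld_from_haplotypes(h)


# ---------------------------------------------------------------------------
# proxy selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProxyAssignment:
    """A genotyped proxy standing in for a target SNP at r2 >= threshold."""

    target_id: str
    proxy_id: str
    r2: float


def select_proxy(
    target: SnpRecord,
    candidates: list[str],
    G: GenotypeMatrix,
    r2_min: float = 0.90,
) -> ProxyAssignment | None:
    """Pick the candidate SNP in strongest LD with the target.

    The target's genotypes must be present in ``G`` (a reference genotype
    set).  If the target itself is among the candidates it is its own proxy
    with r2 = 1.  Otherwise the candidate with maximal EM-based r2 is
    returned, provided it reaches ``r2_min``; ties are broken by smaller
    genomic distance to the target, then lexicographic id.
    """
    if not candidates:
        return None
    if target.snp_id in candidates:
        return ProxyAssignment(target.snp_id, target.snp_id, 1.0)
    if target.snp_id not in G.snp_ids:
        raise ValueError(f"target {target.snp_id} has no genotypes in reference set")

    def distance(cand: str) -> float:
        rec = G.record(cand)
        if rec is None or rec.chrom != target.chrom:
            return float("inf")
        return abs(rec.pos - target.pos)

    scored: list[tuple[float, float, str]] = []
    for cand in candidates:
        if cand not in G.snp_ids:
            continue
        try:
            r2 = ld_between_snps(G, target.snp_id, cand).r2
        except ValueError:
            continue  # monomorphic candidate: no defined LD
        scored.append((-r2, distance(cand), cand))
    if not scored:
        return None
    scored.sort()
    neg_r2, _, best = scored[0]
    if -neg_r2 < r2_min:
        return None
    return ProxyAssignment(target.snp_id, best, -neg_r2)
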