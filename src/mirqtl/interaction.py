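"""Pairwise miSNP x 3utrSNP interaction scan with Levene-weighted
Bonferroni correction, plus replication testing.

The scan regresses probe expression on both dosages and their product term
(all covariate-adjusted) and tests the product coefficient.  Instead of a
flat Bonferroni correction, each test's p-value is divided by a standardized
weight derived from a Levene test of expression-variance equality across the
3utrSNP genotype classes: units whose expression variance differs by
genotype — a fingerprint of an underlying interaction — are prioritized.
Weights average 1 over executed tests, so the family-wise error budget is
conserved and the procedure reduces to standard Bonferroni when all Levene
p-values are equal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CovariateTable, ExpressionMatrix, GenotypeMatrix
from .regression import DegeneratePredictorError, ols, residualize, robust_coef_test

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "ScanDimensions",
    "UtrTestUnit",
    "MiSnpUnit",
    "interaction_model",
    "levene_test",
    "compute_weights",
    "weighted_decision",
    "InteractionScan",
    "InteractionScanResults",
    "run_interaction_scan",
    "replicate_interactions",
]


@dataclass(frozen=True)
class UtrTestUnit:
    """A (3utrSNP, probe) weighting unit.

    Two probes of the same gene are distinct units (they can have different
    Levene p-values); ``utr_proxy`` is the genotyped SNP actually tested.
    """

    gene: str
    probe_id: str
    utr_snp: str
    utr_proxy: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.utr_proxy, self.probe_id)


@dataclass(frozen=True)
class MiSnpUnit:
    """A miSNP analysis unit: target id, genotyped proxy, host miRNA."""

    mi_snp: str
    mi_proxy: str
    mirna: str = ""


@dataclass(frozen=True)
class InteractionRecord:
    """One executed miSNP x 3utrSNP interaction test."""

    gene: str
    probe_id: str
    utr_snp: str
    utr_proxy: str
    mi_snp: str
    mi_proxy: str
    mirna: str
    beta_int: float
    se_int: float
    p_interaction: float
    levene_q: float
    weight: float
    weighted_p: float
    significant: bool
    n_used: int


@dataclass(frozen=True)
class ScanDimensions:
    """Test-count bookkeeping: executed tests define N, not the grid size."""

    n_utr: int
    n_misnp: int
    n_tests: int

    def __post_init__(self) -> None:
        if self.n_tests > self.n_utr * self.n_misnp:
            raise ValueError("more executed tests than grid cells")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def interaction_model(
    y: np.ndarray,
    g_utr: np.ndarray,
    g_mi: np.ndarray,
    covariates: np.ndarray | None = None,
    se: str = "classical",
) -> tuple[float, float, float, int]:
    """OLS of y on [1, g_utr, g_mi, g_utr*g_mi, covariates].

    Returns (beta_int, se_int, p_interaction, n_used) for the product term
    (two-sided t-test).  Complete cases only.  Raises
    :class:`DegeneratePredictorError` on constant predictors or a
    rank-deficient design (e.g. SNPs in perfect LD); callers treat that as a
    skipped test.

    ``se`` selects the standard error for the product-term test:
    ``"classical"`` (homoskedastic OLS), ``"hc3"``, or ``"bm"``
    (HC2 sandwich with Satterthwaite degrees of freedom).  The robust
    options keep the test level close to nominal when residual variance
    depends on genotype — the very situation the Levene weighting
    prioritizes — at the cost of a little power when variances are equal.
    """
    y = np.asarray(y, dtype=float)
    g_utr = np.asarray(g_utr, dtype=float)
    g_mi = np.asarray(g_mi, dtype=float)
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov is not None and cov.shape[0] != len(y):
        cov = cov.T
    mask = np.isfinite(y) & np.isfinite(g_utr) & np.isfinite(g_mi)
    if cov is not None:
        mask &= np.isfinite(cov).all(axis=1)
    y, g_utr, g_mi = y[mask], g_utr[mask], g_mi[mask]
    blocks = [np.ones(len(y)), g_utr, g_mi, g_utr * g_mi]
    names = ["intercept", "g_utr", "g_mi", "g_utr:g_mi"]
    if cov is not None:
        c = cov[mask]
        blocks.append(c)
        names.extend(f"cov{i}" for i in range(c.shape[1]))
    X = np.column_stack(blocks)
    fit = ols(X, y, names=names)
    beta, se_int, p = fit["g_utr:g_mi"]
    if se != "classical":
        j = names.index("g_utr:g_mi")
        sigma2 = fit.rss / fit.df_resid
        resid = y - X @ fit.beta
        se_int, df = robust_coef_test(X, resid, fit.cov / sigma2, j, method=se)
        t = beta / se_int if se_int > 0 else 0.0
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return beta, se_int, p, len(y)


def levene_test(
    y: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    center: str = "mean",
    min_group_n: int = 2,
) -> tuple[float, float]:
    """Levene test of expression-variance equality across genotype classes.

    ``y`` is first residualized on an intercept plus ``covariates`` (the
    same adjustment set as the regression models); the classic Levene
    statistic is then the one-way ANOVA F on z = \\|residual - group center\\|
    with (k-1, n-k) degrees of freedom.  ``center="median"`` gives the
    Brown-Forsythe variant.  Groups smaller than ``min_group_n`` are
    dropped; fewer than two usable groups raises ``ValueError``.

    Returns (F statistic, upper-tail p-value q).
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups, dtype=float)
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov is not None and cov.shape[0] != len(y):
        cov = cov.T
    mask = np.isfinite(y) & np.isfinite(groups)
    if cov is not None:
        mask &= np.isfinite(cov).all(axis=1)
    y, groups = y[mask], groups[mask]
    resid = residualize(y, None if cov is None else cov[mask])

    zs = []
    for gval in np.unique(groups):
        r = resid[groups == gval]
        if len(r) < min_group_n:
            continue
        c = np.median(r) if center == "median" else r.mean()
        zs.append(np.abs(r - c))
    k = len(zs)
    if k < 2:
        raise ValueError("Levene test undefined: <2 usable genotype groups")
    n = sum(len(z) for z in zs)
    grand = np.concatenate(zs).mean()
    ssb = sum(len(z) * (z.mean() - grand) ** 2 for z in zs)
    ssw = sum(((z - z.mean()) ** 2).sum() for z in zs)
    if ssw == 0.0:
        return float("inf"), 0.0
    F = (ssb / (k - 1)) / (ssw / (n - k))
    q = float(stats.f.sf(F, k - 1, n - k))
    return float(F), q


_Q_FLOOR = 1e-300  # guards -log against q underflowing to exactly 0


def compute_weights(
    levene_q: Mapping[object, float],
    test_units: Sequence[object],
) -> dict[object, float]:
    """Standardized weights w_u proportional to -log(q_u), mean 1 over tests.

    ``test_units`` lists, per executed test, the weighting unit it belongs
    to (a unit appears once per test using it).  Each test contributes its
    unit's -log q to the normalization, so the weights assigned across the N
    executed tests sum to N.  The log base cancels.  If every q equals 1
    the weights are undefined (0/0) and fall back to uniform 1 (standard
    Bonferroni).
    """
    N = len(test_units)
    if N == 0:
        return {}
    neglog = {
        u: -math.log(max(q, _Q_FLOOR)) for u, q in levene_q.items()
    }
    total = sum(neglog[u] for u in test_units)
    if total == 0.0:
        logger.warning("all Levene p-values are 1; falling back to uniform weights")
        return {u: 1.0 for u in levene_q}
    return {u: neglog[u] * N / total for u in neglog}


def weighted_decision(
    p_interaction: float,
    weight: float,
    alpha: float = 0.05,
    n_tests: int = 1,
) -> tuple[float, bool]:
    """Weighted p-value P* = P / w and the genome-wide call P* < alpha / N."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    weighted_p = p_interaction / weight
    return weighted_p, bool(weighted_p < alpha / n_tests)


# ---------------------------------------------------------------------------
# the scan model
# ---------------------------------------------------------------------------

class InteractionScan:
    """Genome-wide miSNP x 3utrSNP interaction scan model.

    Every 3utrSNP unit (a genotyped 3'UTR proxy paired with a probe of its
    gene) is tested against every miSNP proxy.  One Levene p-value is
    computed per unit on covariate-residualized expression; weights are
    standardized over executed tests.

    Parameters
    ----------
    expression, genotypes, covariates
        Core data, aligned by sample id.
    units : sequence of UtrTestUnit
    misnps : sequence of MiSnpUnit
    center : {"mean", "median"}
        Deviation center for the Levene statistic (median = Brown-Forsythe).
    weighting : {"levene", "none"}
        "none" forces uniform weights (standard Bonferroni).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        genotypes: GenotypeMatrix,
        covariates: CovariateTable | None,
        units: Sequence[UtrTestUnit],
        misnps: Sequence[MiSnpUnit],
        center: str = "mean",
        weighting: str = "levene",
        min_group_n: int = 2,
        include_status: bool = False,
        se: str = "bm",
    ):
        if se not in ("classical", "hc3", "bm"):
            raise ValueError(f"unknown se {se!r}")
        if center not in ("mean", "median"):
            raise ValueError(f"unknown center {center!r}")
        if weighting not in ("levene", "none"):
            raise ValueError(f"unknown weighting {weighting!r}")
        samples = expression.sample_ids.intersection(genotypes.sample_ids, sort=False)
        if covariates is not None:
            samples = samples.intersection(covariates.sample_ids, sort=False)
        if len(samples) == 0:
            raise ValueError("no shared samples across inputs")
        self.samples = samples
        self.expression = expression
        self.genotypes = genotypes
        self.covariates = covariates
        self.units = list(units)
        self.misnps = list(misnps)
        self.center = center
        self.weighting = weighting
        self.min_group_n = min_group_n
        self.include_status = include_status
        self.se = se

    def fit(self, alpha: float = 0.05) -> "InteractionScanResults":
        cov = (
            self.covariates.design_columns(self.include_status)
            .loc[self.samples]
            .to_numpy()
            if self.covariates is not None
            else None
        )
        E = self.expression.values.loc[self.samples]
        G = self.genotypes.dosages.loc[self.samples]

        # one Levene q per usable unit
        levene_q: dict[tuple[str, str], float] = {}
        skipped: list[dict] = []
        usable_units: list[UtrTestUnit] = []
        for unit in self.units:
            if unit.probe_id not in E.columns or unit.utr_proxy not in G.columns:
                skipped.append({"unit": unit, "mi_proxy": None, "reason": "missing data column"})
                continue
            try:
                _, q = levene_test(
                    E[unit.probe_id].to_numpy(),
                    G[unit.utr_proxy].to_numpy(),
                    covariates=cov,
                    center=self.center,
                    min_group_n=self.min_group_n,
                )
            except ValueError as exc:
                logger.warning("unit %s dropped from weighting: %s", unit.key, exc)
                skipped.append({"unit": unit, "mi_proxy": None, "reason": str(exc)})
                continue
            levene_q[unit.key] = q
            usable_units.append(unit)

        # interaction fits over the executed grid
        raw: list[tuple[UtrTestUnit, MiSnpUnit, float, float, float, int]] = []
        for unit in usable_units:
            y = E[unit.probe_id].to_numpy()
            g_u = G[unit.utr_proxy].to_numpy()
            for mi in self.misnps:
                if mi.mi_proxy not in G.columns:
                    skipped.append({"unit": unit, "mi_proxy": mi.mi_proxy, "reason": "missing data column"})
                    continue
                try:
                    b, se, p, n_used = interaction_model(
                        y, g_u, G[mi.mi_proxy].to_numpy(), cov, se=self.se
                    )
                except DegeneratePredictorError as exc:
                    skipped.append({"unit": unit, "mi_proxy": mi.mi_proxy, "reason": str(exc)})
                    continue
                raw.append((unit, mi, b, se, p, n_used))

        n_tests = len(raw)
        if self.weighting == "levene":
            weights = compute_weights(levene_q, [u.key for u, *_ in raw])
        else:
            weights = {u.key: 1.0 for u in usable_units}

        records = []
        for unit, mi, b, se, p, n_used in raw:
            w = weights.get(unit.key, 1.0)
            wp, sig = weighted_decision(p, w, alpha, max(n_tests, 1))
            records.append(
                InteractionRecord(
                    gene=unit.gene, probe_id=unit.probe_id,
                    utr_snp=unit.utr_snp, utr_proxy=unit.utr_proxy,
                    mi_snp=mi.mi_snp, mi_proxy=mi.mi_proxy, mirna=mi.mirna,
                    beta_int=b, se_int=se, p_interaction=p,
                    levene_q=levene_q.get(unit.key, 1.0),
                    weight=w, weighted_p=wp, significant=sig, n_used=n_used,
                )
            )
        records.sort(key=lambda r: (r.weighted_p, r.probe_id, r.utr_snp, r.mi_snp))
        dims = ScanDimensions(
            n_utr=len(usable_units), n_misnp=len(self.misnps), n_tests=n_tests
        )
        return InteractionScanResults(self, records, dims, skipped, alpha)


class InteractionScanResults:
    """Interaction-scan results: records, dimensions, decisions, summary."""

    def __init__(
        self,
        model: InteractionScan,
        records: list[InteractionRecord],
        dimensions: ScanDimensions,
        skipped: list[dict],
        alpha: float,
    ):
        self.model = model
        self.records = records
        self.dimensions = dimensions
        self.skipped = skipped
        self.alpha = alpha

    @property
    def threshold(self) -> float:
        """alpha / N over executed tests."""
        return self.alpha / self.dimensions.n_tests if self.dimensions.n_tests else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def significant(self) -> list[InteractionRecord]:
        return [r for r in self.records if r.significant]

    def summary(self, top: int = 10) -> str:
        d = self.dimensions
        lines = [
            "miSNP x 3utrSNP interaction scan (Levene-weighted Bonferroni)"
            if self.model.weighting == "levene"
            else "miSNP x 3utrSNP interaction scan (standard Bonferroni)",
            f"  samples: {len(self.model.samples)}",
            f"  units (3utrSNP proxy x probe): {d.n_utr}   miSNPs: {d.n_misnp}",
            f"  executed tests N: {d.n_tests}   skipped: {len(self.skipped)}",
            f"  significance threshold alpha/N: {self.threshold:.3g} (alpha={self.alpha})",
            f"  significant interactions: {len(self.significant())}",
        ]
        df = self.to_frame()
        if not df.empty:
            cols = [
                "gene", "probe_id", "utr_proxy", "mi_proxy",
                "p_interaction", "levene_q", "weighted_p", "significant",
            ]
            lines.append(df[cols].head(top).to_string(index=False))
        return "\n".join(lines)


def run_interaction_scan(
    expression: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    covariates: CovariateTable | None,
    units: Sequence[UtrTestUnit],
    misnps: Sequence[MiSnpUnit],
    alpha: float = 0.05,
    **kwargs,
) -> InteractionScanResults:
    """Functional wrapper over :class:`InteractionScan`."""
    return InteractionScan(
        expression, genotypes, covariates, units, misnps, **kwargs
    ).fit(alpha=alpha)


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

def replicate_interactions(
    hits: Sequence[InteractionRecord],
    expression: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    covariates: CovariateTable | None,
    proxy_map: Mapping[str, str] | None = None,
    probe_map: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    check_sign: bool = True,
    se: str = "bm",
) -> pd.DataFrame:
    """Test discovery interaction hits in an independent replication cohort.

    Each hit is re-fitted with the same interaction model (disease status
    appended to the covariates when available) using replication proxies
    given by ``proxy_map`` (discovery SNP id -> replication SNP id; identity
    by default).  Hits whose proxies or probe are absent from the
    replication data are marked non-replicable and excluded from the
    Bonferroni denominator k; a hit replicates iff p < alpha / k and
    (optionally) its interaction coefficient has the discovery sign.
    """
    proxy_map = dict(proxy_map or {})
    probe_map = dict(probe_map or {})
    samples = expression.sample_ids.intersection(genotypes.sample_ids, sort=False)
    if covariates is not None:
        samples = samples.intersection(covariates.sample_ids, sort=False)
    cov = (
        covariates.design_columns(include_status=True).loc[samples].to_numpy()
        if covariates is not None
        else None
    )
    E = expression.values.loc[samples]
    G = genotypes.dosages.loc[samples]

    rows = []
    for hit in hits:
        utr = proxy_map.get(hit.utr_proxy, hit.utr_proxy)
        mi = proxy_map.get(hit.mi_proxy, hit.mi_proxy)
        probe = probe_map.get(hit.probe_id, hit.probe_id)
        replicable = utr in G.columns and mi in G.columns and probe in E.columns
        row = {
            "gene": hit.gene, "probe_id": probe,
            "utr_proxy": utr, "mi_proxy": mi,
            "discovery_beta_int": hit.beta_int,
            "discovery_weighted_p": hit.weighted_p,
            "replicable": replicable,
            "beta_int": np.nan, "se_int": np.nan, "p": np.nan,
        }
        if replicable:
            try:
                b, se_int, p, _ = interaction_model(
                    E[probe].to_numpy(), G[utr].to_numpy(), G[mi].to_numpy(), cov, se=se
                )
                row.update(beta_int=b, se_int=se_int, p=p)
            except DegeneratePredictorError as exc:
                logger.warning("replication fit skipped for %s: %s", utr, exc)
                row["replicable"] = False
        rows.append(row)

    if not rows:
        return pd.DataFrame(
            columns=[
                "gene", "probe_id", "utr_proxy", "mi_proxy",
                "discovery_beta_int", "discovery_weighted_p", "replicable",
                "beta_int", "se_int", "p", "k", "threshold", "replicated",
            ]
        )
    df = pd.DataFrame(rows)
    k = int(df["replicable"].sum())
    threshold = alpha / k if k else float("nan")
    df["k"] = k
    df["threshold"] = threshold
    sign_ok = (
        np.sign(df["beta_int"]) == np.sign(df["discovery_beta_int"])
        if check_sign
        else True
    )
    df["replicated"] = df["replicable"] & (df["p"] < threshold) & sign_ok
    return df
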