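"""Marginal additive SNP -> expression association, cis/trans classification
and conditional (eSNP- or mediator-adjusted) models.

The model is ordinary least squares of a probe's (normalized, log-scale)
expression on minor-allele dosage under additive allele effects, adjusted
for age and sex (and disease status where present).  The per-SNP R^2 is the
increment in model R^2 attributable to the dosage term, mirroring how
published eQTL tables report variance explained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CovariateTable,
    ExpressionMatrix,
    GenomicInterval,
    GenotypeMatrix,
    SnpRecord,
)
from .regression import DegeneratePredictorError, ols

__all__ = [
    "AssociationResult",
    "fit_additive_model",
    "classify_cis_trans",
    "find_best_cis_esnp",
    "conditional_association",
    "correlation_matrix",
    "AssociationScan",
    "AssociationScanResults",
]

CIS_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class AssociationResult:
    """One SNP x probe additive association."""

    snp_id: str
    probe_id: str
    beta: float          # expression units per minor-allele copy
    se: float
    p: float
    r2_increment: float  # fraction of variance explained by the dosage term
    n_used: int
    covariates: tuple[str, ...]
    cis_trans: str = "unknown"  # "cis" | "trans" | "unknown"


def _complete_cases(*arrays: np.ndarray) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        if a is None:
            continue
        a = np.asarray(a, dtype=float)
        mask &= np.isfinite(a) if a.ndim == 1 else np.isfinite(a).all(axis=1)
    return mask


def fit_additive_model(
    y: np.ndarray,
    g: np.ndarray,
    covariates: np.ndarray | None = None,
    extra_covariates: np.ndarray | None = None,
    snp_id: str = "snp",
    probe_id: str = "probe",
    covariate_names: Sequence[str] = (),
) -> AssociationResult:
    """Additive-effect OLS of expression on minor-allele dosage.

    Complete cases only; ``covariates``/``extra_covariates`` are 2-D arrays
    appended to the design after the dosage term.  Returns the dosage
    coefficient with its two-sided t-test p-value and the R^2 increment of
    the dosage term over the covariate-only model.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov is not None and cov.shape[0] != len(y):
        cov = cov.T
    extra = None if extra_covariates is None else np.atleast_2d(np.asarray(extra_covariates, dtype=float))
    if extra is not None and extra.shape[0] != len(y):
        extra = extra.T

    mask = _complete_cases(y, g, cov, extra)
    y, g = y[mask], g[mask]
    blocks = [np.ones(len(y)), g]
    names = ["intercept", "g"]
    for block, label in ((cov, "cov"), (extra, "adj")):
        if block is not None:
            block = block[mask]
            blocks.append(block)
            names.extend(
                covariate_names[i] if label == "cov" and i < len(covariate_names)
                else f"{label}{i}"
                for i in range(block.shape[1])
            )
    X = np.column_stack(blocks)
    fit = ols(X, y, names=names)

    # R^2 increment of the dosage term over the reduced model
    X_red = np.delete(X, 1, axis=1)
    red = ols(X_red, y, names=[n for n in names if n != "g"]) if X_red.shape[1] > 1 else None
    if red is None:
        r2_red = 0.0
    else:
        r2_red = red.r2
    beta, se, p = fit["g"]
    return AssociationResult(
        snp_id=snp_id,
        probe_id=probe_id,
        beta=beta,
        se=se,
        p=p,
        r2_increment=max(fit.r2 - r2_red, 0.0),
        n_used=int(mask.sum()),
        covariates=tuple(names[2:]),
    )


def classify_cis_trans(
    snp: SnpRecord,
    probe_interval: GenomicInterval,
    window: int = CIS_WINDOW_BP,
) -> str:
    """cis iff same chromosome and within ``window`` bp of the probe interval.

    Distance is measured to the nearest edge of the probe's annotated
    interval; a distance exactly equal to the window is cis (closed
    boundary).  A SNP on a different chromosome is trans.
    """
    if not snp.chrom or not probe_interval.chrom:
        raise ValueError("unknown chromosome label")
    d = probe_interval.distance_to(snp.chrom, snp.pos)
    if d is None:
        return "trans"
    return "cis" if d <= window else "trans"


def find_best_cis_esnp(
    probe_id: str,
    results: Sequence[AssociationResult],
    p_max: float = 5.5e-5,
    ) -> str | None:
    """Best cis eSNP: the cis SNP with smallest association p below ``p_max``.

    ``results`` must already carry cis/trans labels relative to this probe.
    Ties on p are broken by larger \\|beta\\|, then lexicographic SNP id.  The
    tested SNP itself may win (the best cis eSNP and the tested SNP can
    coincide).
    """
    cands = [
        r for r in results
        if r.probe_id == probe_id and r.cis_trans == "cis" and r.p < p_max
    ]
    if not cands:
        return None
    cands.sort(key=lambda r: (r.p, -abs(r.beta), r.snp_id))
    return cands[0].snp_id


def conditional_association(
    y: np.ndarray,
    g: np.ndarray,
    covariates: np.ndarray | None,
    adjusters: np.ndarray,
    **kwargs,
) -> AssociationResult:
    """Additive model with adjusters (eSNP dosages and/or mediator
    expression vectors) appended as covariates.

    Raises :class:`DegeneratePredictorError` when an adjuster is collinear
    with the dosage term (e.g. a copy of ``g``).
    """
    return fit_additive_model(
        y, g, covariates=covariates, extra_covariates=adjusters, **kwargs
    )


def correlation_matrix(
    E: ExpressionMatrix,
    probe_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson correlations between probes (complete cases per pair).

    Diagonal is 1; a zero-variance probe yields NaN entries (flagged via a
    warning by pandas semantics — NaN marks the undefined correlations).
    """
    df = E.values if probe_ids is None else E.values[list(probe_ids)]
    if len(df) < 3:
        raise ValueError("need >=3 samples for a correlation matrix")
    corr = df.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    return corr


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

class AssociationScan:
    """Marginal eQTL scan model: every (SNP, probe) additive association.

    Parameters
    ----------
    expression, genotypes, covariates
        Core data; samples are aligned by id (intersection, order of the
        expression matrix).
    probe_intervals : mapping, optional
        Probe id -> genomic interval, enabling cis/trans classification.
    snp_ids, probe_ids : sequences, optional
        Restrict the scan; defaults to everything present.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        genotypes: GenotypeMatrix,
        covariates: CovariateTable | None = None,
        probe_intervals: Mapping[str, GenomicInterval] | None = None,
        snp_ids: Sequence[str] | None = None,
        probe_ids: Sequence[str] | None = None,
        window: int = CIS_WINDOW_BP,
        include_status: bool = False,
    ):
        samples = expression.sample_ids.intersection(genotypes.sample_ids, sort=False)
        if covariates is not None:
            samples = samples.intersection(covariates.sample_ids, sort=False)
        if len(samples) == 0:
            raise ValueError("no shared samples across inputs")
        self.samples = samples
        self.expression = expression
        self.genotypes = genotypes
        self.covariates = covariates
        self.probe_intervals = dict(probe_intervals or {})
        self.snp_ids = list(snp_ids) if snp_ids is not None else list(genotypes.snp_ids)
        self.probe_ids = list(probe_ids) if probe_ids is not None else list(expression.probe_ids)
        self.window = int(window)
        self.include_status = include_status

    def _cov_block(self) -> tuple[np.ndarray | None, tuple[str, ...]]:
        if self.covariates is None:
            return None, ()
        cols = self.covariates.design_columns(self.include_status)
        return cols.loc[self.samples].to_numpy(), tuple(cols.columns)

    def fit(self, alpha: float = 0.05) -> "AssociationScanResults":
        cov, cov_names = self._cov_block()
        records: list[AssociationResult] = []
        skipped: list[tuple[str, str, str]] = []
        for probe_id in self.probe_ids:
            y = self.expression.values.loc[self.samples, probe_id].to_numpy()
            iv = self.probe_intervals.get(probe_id)
            for snp_id in self.snp_ids:
                g = self.genotypes.dosages.loc[self.samples, snp_id].to_numpy()
                try:
                    res = fit_additive_model(
                        y, g, covariates=cov, snp_id=snp_id, probe_id=probe_id,
                        covariate_names=cov_names,
                    )
                except DegeneratePredictorError as exc:
                    skipped.append((snp_id, probe_id, str(exc)))
                    continue
                rec = self.genotypes.record(snp_id)
                label = (
                    classify_cis_trans(rec, iv, self.window)
                    if rec is not None and iv is not None
                    else "unknown"
                )
                records.append(
                    AssociationResult(**{**res.__dict__, "cis_trans": label})
                )
        return AssociationScanResults(self, records, skipped, alpha)


class AssociationScanResults:
    """Results of a marginal scan, with Bonferroni decisions and summary."""

    def __init__(
        self,
        model: AssociationScan,
        records: list[AssociationResult],
        skipped: list[tuple[str, str, str]],
        alpha: float,
    ):
        self.model = model
        self.records = records
        self.skipped = skipped
        self.alpha = alpha
        self.n_snps_tested = len({r.snp_id for r in records})
        self.n_probes_tested = len({r.probe_id for r in records})

    @property
    def bonferroni_threshold(self) -> float:
        """alpha / (n SNPs tested x n probes tested), never hard-coded."""
        denom = self.n_snps_tested * self.n_probes_tested
        return self.alpha / denom if denom else float("nan")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.__dict__ for r in self.records])
        if df.empty:
            return df
        df["significant"] = df["p"] < self.bonferroni_threshold
        return df.sort_values(["p", "probe_id", "snp_id"], kind="mergesort").reset_index(drop=True)

    def significant(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[df["significant"]] if not df.empty else df

    def summary(self, top: int = 10) -> str:
        df = self.to_frame()
        lines = [
            "Marginal additive eQTL scan",
            f"  samples: {len(self.model.samples)}",
            f"  SNPs tested: {self.n_snps_tested}  probes tested: {self.n_probes_tested}",
            f"  Bonferroni threshold: {self.bonferroni_threshold:.3g} (alpha={self.alpha})",
            f"  significant associations: {0 if df.empty else int(df['significant'].sum())}",
            f"  skipped (degenerate): {len(self.skipped)}",
        ]
        if not df.empty:
            cols = ["snp_id", "probe_id", "beta", "se", "p", "r2_increment", "cis_trans"]
            lines.append(df[cols].head(top).to_string(index=False))
        return "\n".join(lines)
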