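"""Two-SNP haplotype-effect regression and effect-homogeneity testing.

Haplotype effects are estimated by OLS on posterior-expected haplotype
dosages: for every sample the expected number of copies (0-2) of each of
the four two-locus haplotypes is computed from the EM haplotype
frequencies; only double heterozygotes are phase-ambiguous and receive
fractional dosages.  This deterministic expected-dosage substitution stands
in for stochastic-EM multiple imputation; it slightly understates
uncertainty when the double-heterozygote fraction is high (documented
limitation).  Effects are per-copy contrasts against the most frequent
(reference) haplotype, assuming additive haplotype effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genetics import HaplotypeFreqs, em_haplotype_frequencies
from .regression import DegeneratePredictorError, OlsFit, ols

logger = logging.getLogger(__name__)

__all__ = [
    "HAPLOTYPE_ORDER",
    "expected_haplotype_dosages",
    "HaplotypeEffectResult",
    "haplotype_effect_regression",
    "homogeneity_test",
    "HaplotypeEffectModel",
]

#: Haplotype order matching :class:`HaplotypeFreqs`: A/B are the major
#: (dosage-reference) alleles, a/b the minor (dosage-counted) alleles.
HAPLOTYPE_ORDER = ("AB", "Ab", "aB", "ab")

# genotype pair (d1, d2) -> haplotype index pair, unambiguous cases
_UNAMBIGUOUS = {
    (0, 0): (0, 0), (0, 1): (0, 1), (0, 2): (1, 1),
    (1, 0): (0, 2), (1, 2): (1, 3),
    (2, 0): (2, 2), (2, 1): (2, 3), (2, 2): (3, 3),
}


def expected_haplotype_dosages(
    g1: np.ndarray,
    g2: np.ndarray,
    h: HaplotypeFreqs,
) -> np.ndarray:
    """Per-sample expected copies of each haplotype (n x 4, order AB,Ab,aB,ab).

    Unambiguous genotype pairs give integer counts; double heterozygotes get
    posterior-expected counts under ``h``.  Rows with a missing genotype are
    NaN.  Every complete row sums to 2.  An observed unambiguous genotype
    requiring a zero-frequency haplotype raises ``ValueError`` (the supplied
    frequencies are inconsistent with the data).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    f = h.as_array()
    n = len(g1)
    out = np.full((n, 4), np.nan)
    complete = np.isfinite(g1) & np.isfinite(g2)

    # posterior probability of the AB/ab phase for double heterozygotes
    denom = f[0] * f[3] + f[1] * f[2]
    p_cis = 0.5 if denom == 0 else f[0] * f[3] / denom

    for i in np.nonzero(complete)[0]:
        key = (int(g1[i]), int(g2[i]))
        row = np.zeros(4)
        if key == (1, 1):
            row[[0, 3]] = p_cis
            row[[1, 2]] = 1.0 - p_cis
        else:
            a, b = _UNAMBIGUOUS[key]
            if f[a] == 0.0 or f[b] == 0.0:
                raise ValueError(
                    f"genotype pair {key} observed but haplotype "
                    f"{HAPLOTYPE_ORDER[a] if f[a] == 0 else HAPLOTYPE_ORDER[b]} "
                    "has frequency 0: frequencies inconsistent with data"
                )
            row[a] += 1.0
            row[b] += 1.0
        out[i] = row
    return out


@dataclass
class HaplotypeEffectResult:
    """Per-haplotype additive effects relative to the reference haplotype."""

    labels: tuple[str, ...]
    frequencies: dict[str, float]
    reference: str
    beta: dict[str, float]                    # reference maps to 0.0
    ci95: dict[str, tuple[float, float]]
    global_r2: float
    global_p: float
    covariates: tuple[str, ...]
    n_used: int
    estimable: tuple[str, ...] = ()
    _fit: OlsFit | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            "Two-SNP haplotype effects (additive, expected-dosage regression)",
            f"  n = {self.n_used}; reference haplotype: {self.reference} "
            f"(freq {self.frequencies[self.reference]:.3f})",
            f"  covariates: {list(self.covariates) or 'none'}",
            "  haplotype   freq     beta   95% CI",
        ]
        for lab in self.labels:
            if lab == self.reference:
                lines.append(f"  {lab:<10}  {self.frequencies[lab]:.3f}  reference")
            elif lab in self.beta:
                lo, hi = self.ci95[lab]
                lines.append(
                    f"  {lab:<10}  {self.frequencies[lab]:.3f}  "
                    f"{self.beta[lab]:+.3f}  [{lo:+.3f} - {hi:+.3f}]"
                )
            else:
                lines.append(f"  {lab:<10}  {self.frequencies[lab]:.3f}  inestimable")
        lines.append(
            f"  haplotypic association: R2 = {100 * self.global_r2:.2f}%  "
            f"p = {self.global_p:.3g}"
        )
        return "\n".join(lines)


def haplotype_effect_regression(
    y: np.ndarray,
    dosages: np.ndarray,
    covariates: np.ndarray | None = None,
    frequencies: HaplotypeFreqs | None = None,
    labels: tuple[str, ...] = HAPLOTYPE_ORDER,
    covariate_names: tuple[str, ...] = (),
) -> HaplotypeEffectResult:
    """OLS of expression on non-reference haplotype dosages + covariates.

    The reference is the most frequent haplotype (ties broken
    lexicographically by label); coefficients are per-copy effects versus
    that reference, with t-based 95% CIs.  The global p is the F-test of all
    haplotype terms, and the global R^2 is the increment of the haplotype
    terms over the covariate-only model.  Haplotypes carried by nobody are
    inestimable and dropped with a warning.
    """
    y = np.asarray(y, dtype=float)
    dosages = np.asarray(dosages, dtype=float)
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov is not None and cov.shape[0] != len(y):
        cov = cov.T
    mask = np.isfinite(y) & np.isfinite(dosages).all(axis=1)
    if cov is not None:
        mask &= np.isfinite(cov).all(axis=1)
    y, dosages = y[mask], dosages[mask]
    if cov is not None:
        cov = cov[mask]

    if frequencies is not None:
        freqs = dict(zip(labels, frequencies.as_array()))
    else:
        freqs = dict(zip(labels, dosages.mean(axis=0) / 2.0))
    reference = max(labels, key=lambda l: (freqs[l], [-ord(c) for c in l]))

    estimable = [
        lab for i, lab in enumerate(labels)
        if lab != reference and dosages[:, i].max() > 0
    ]
    dropped = [lab for lab in labels if lab != reference and lab not in estimable]
    if dropped:
        logger.warning("haplotypes carried by nobody, inestimable: %s", dropped)

    def build(est):
        blocks = [np.ones(len(y))] + [dosages[:, labels.index(lab)] for lab in est]
        names = ["intercept"] + [f"hap:{lab}" for lab in est]
        if cov is not None:
            blocks.append(cov)
            names.extend(
                covariate_names[i] if i < len(covariate_names) else f"cov{i}"
                for i in range(cov.shape[1])
            )
        return np.column_stack(blocks), names

    # collapse to the estimable set: very rare haplotypes can leave a
    # (near-)rank-deficient design; drop the offending columns and refit
    while True:
        X, names = build(estimable)
        try:
            fit = ols(X, y, names=names)
            break
        except DegeneratePredictorError as exc:
            bad = [lab for lab in estimable if f"hap:{lab}" in str(exc)]
            if not bad:
                raise
            logger.warning("collapsing inestimable haplotype column(s): %s", bad)
            estimable = [lab for lab in estimable if lab not in bad]
            if not estimable:
                raise

    hap_names = [f"hap:{lab}" for lab in estimable]
    _, global_p = fit.f_test(hap_names)
    # R^2 increment of the haplotype terms over the covariate-only model
    keep = [i for i, nm in enumerate(names) if nm not in hap_names]
    if len(keep) > 1:
        red = ols(X[:, keep], y, names=[names[i] for i in keep])
        r2_red = red.r2
    else:
        r2_red = 0.0

    tcrit = stats.t.ppf(0.975, fit.df_resid)
    beta = {reference: 0.0}
    ci: dict[str, tuple[float, float]] = {reference: (0.0, 0.0)}
    for lab in estimable:
        b, se, _ = fit[f"hap:{lab}"]
        beta[lab] = b
        ci[lab] = (b - tcrit * se, b + tcrit * se)

    return HaplotypeEffectResult(
        labels=tuple(labels),
        frequencies=freqs,
        reference=reference,
        beta=beta,
        ci95=ci,
        global_r2=max(fit.r2 - r2_red, 0.0),
        global_p=global_p,
        covariates=tuple(names[1 + len(estimable):]),
        n_used=len(y),
        estimable=tuple([reference] + estimable),
        _fit=fit,
    )


def homogeneity_test(result: HaplotypeEffectResult) -> tuple[float, float]:
    """Wald test that the locus-1 allele effect is equal on both locus-2
    backgrounds.

    H0: [beta(AB) - beta(aB)] = [beta(Ab) - beta(ab)], i.e. the contrast
    beta(AB) - beta(aB) - beta(Ab) + beta(ab) = 0 on the coefficient
    covariance matrix.  This is the haplotype-scale parameterization of the
    dosage-product interaction.  Requires all four haplotypes estimable.

    Returns (contrast estimate, p-value).
    """
    if set(result.estimable) != set(HAPLOTYPE_ORDER) or result._fit is None:
        raise ValueError("homogeneity test unavailable: not all four haplotypes estimable")
    signs = {"AB": 1.0, "Ab": -1.0, "aB": -1.0, "ab": 1.0}
    fit = result._fit
    c = np.zeros(len(fit.names))
    for lab, s in signs.items():
        if lab == result.reference:
            continue  # reference coefficient is identically 0
        c[fit.names.index(f"hap:{lab}")] = s
    est, _, p = fit.contrast(c)
    return est, p


class HaplotypeEffectModel:
    """Two-SNP haplotype-effect model for one expression trait.

    EM haplotype frequencies are estimated from the two dosage vectors, each
    sample gets posterior-expected haplotype dosages, and expression is
    regressed on the non-reference dosages plus covariates.
    ``fit()`` returns a :class:`HaplotypeEffectResult`; pass it to
    :func:`homogeneity_test` for the background-homogeneity Wald test.
    """

    def __init__(
        self,
        y: np.ndarray,
        g1: np.ndarray,
        g2: np.ndarray,
        covariates: np.ndarray | None = None,
        covariate_names: tuple[str, ...] = (),
    ):
        self.y = np.asarray(y, dtype=float)
        self.g1 = np.asarray(g1, dtype=float)
        self.g2 = np.asarray(g2, dtype=float)
        self.covariates = covariates
        self.covariate_names = covariate_names
        self.frequencies = em_haplotype_frequencies(self.g1, self.g2)

    def fit(self) -> HaplotypeEffectResult:
        dosages = expected_haplotype_dosages(self.g1, self.g2, self.frequencies)
        return haplotype_effect_regression(
            self.y,
            dosages,
            covariates=self.covariates,
            frequencies=self.frequencies,
            covariate_names=self.covariate_names,
        )
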