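"""Small ordinary-least-squares core shared by the association, interaction
and haplotype models.

The designs here are tiny (an intercept, one to four genetic terms, a
handful of covariates), but millions of them are fitted in a genome-wide
scan, so the core is a direct normal-equations solve with explicit rank
checking rather than a heavyweight model object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["OlsFit", "DegeneratePredictorError", "ols", "residualize"]


class DegeneratePredictorError(ValueError):
    """Raised when a predictor is constant or the design is rank deficient."""


@dataclass
class OlsFit:
    """OLS estimates, their covariance and the usual diagnostics."""

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    cov: np.ndarray          # sigma^2 (X'X)^-1
    df_resid: int
    rss: float
    tss: float
    n: int
    names: tuple[str, ...]

    @property
    def r2(self) -> float:
        return 1.0 - self.rss / self.tss if self.tss > 0 else 0.0

    def __getitem__(self, name: str) -> tuple[float, float, float]:
        """(beta, se, p) for a named column."""
        i = self.names.index(name)
        return float(self.beta[i]), float(self.se[i]), float(self.p[i])

    def f_test(self, names: Sequence[str]) -> tuple[float, float]:
        """Wald F-test that the named coefficients are jointly zero."""
        idx = [self.names.index(n) for n in names]
        b = self.beta[idx]
        V = self.cov[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b)) / len(idx)
        p = float(stats.f.sf(stat, len(idx), self.df_resid))
        return stat, p

    def contrast(self, c: np.ndarray) -> tuple[float, float, float]:
        """Wald test of the linear contrast c'beta = 0: (estimate, se, p)."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        var = float(c @ self.cov @ c)
        se = np.sqrt(var)
        if se == 0.0:
            return est, 0.0, 1.0 if est == 0.0 else 0.0
        t = est / se
        p = 2.0 * float(stats.t.sf(abs(t), self.df_resid))
        return est, se, p


def ols(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    rank_tol: float = 1e-8,
) -> OlsFit:
    """Fit y = X beta + e by ordinary least squares.

    ``X`` must include the intercept column if one is wanted.  Raises
    :class:`DegeneratePredictorError` on constant non-intercept columns or a
    rank-deficient design, naming the offending columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if names is None:
        names = tuple(f"x{i}" for i in range(k))
    else:
        names = tuple(names)
    if n < k + 2:
        raise DegeneratePredictorError(f"too few observations: n={n}, k={k}")

    # constant non-intercept columns are degenerate predictors
    spans = X.max(axis=0) - X.min(axis=0)
    const = [names[i] for i in range(k) if spans[i] == 0 and names[i] != "intercept"]
    if const:
        raise DegeneratePredictorError(f"constant predictor column(s): {const}")

    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.size else 0.0
    if scale == 0.0 or (diag < rank_tol * scale).any():
        bad = [names[i] for i in range(k) if diag[i] < rank_tol * scale]
        raise DegeneratePredictorError(f"rank-deficient design; collinear column(s): {bad}")

    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = n - k
    sigma2 = rss / df_resid
    rinv = np.linalg.inv(r)
    cov = sigma2 * (rinv @ rinv.T)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_resid)
    tss = float(((y - y.mean()) ** 2).sum())
    return OlsFit(
        beta=beta, se=se, t=t, p=p, cov=cov,
        df_resid=df_resid, rss=rss, tss=tss, n=n, names=names,
    )


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of y after OLS on an intercept plus covariates."""
    y = np.asarray(y, dtype=float)
    if covariates is None or covariates.size == 0:
        return y - y.mean()
    X = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def robust_coef_test(
    X: np.ndarray,
    resid: np.ndarray,
    cov_unscaled: np.ndarray,
    j: int,
    method: str = "bm",
) -> tuple[float, float]:
    """Heteroskedasticity-robust (se, df) for coefficient j.

    ``cov_unscaled`` is (X'X)^-1.  ``method="hc3"`` gives the HC3 sandwich
    with the usual n - k degrees of freedom; ``method="bm"`` gives the
    HC2 sandwich with Satterthwaite degrees of freedom computed under
    homoskedasticity (Bell-McCaffrey small-sample correction), which keeps
    far-tail test levels close to nominal even when the coefficient's
    information is concentrated in a few observations.  The caller forms
    t = beta_j / se and refers it to a t distribution on ``df``.
    """
    n, k = X.shape
    a = X @ cov_unscaled[:, j]
    h = np.einsum("ij,jk,ik->i", X, cov_unscaled, X)
    h = np.minimum(h, 1.0 - 1e-12)
    if method == "hc3":
        u2 = (resid / (1.0 - h)) ** 2
        V = float(np.sum(a * a * u2))
        return np.sqrt(V), float(n - k)
    if method != "bm":
        raise ValueError(f"unknown robust method {method!r}")
    u2 = resid**2 / (1.0 - h)  # HC2
    V = float(np.sum(a * a * u2))
    # Satterthwaite df of V under homoskedasticity: S = (I-H) D (I-H),
    # D = diag(a_i^2 / (1-h_i)); tr(S^2) computed in O(n k^2) via the
    # rank-k structure of H.
    d = a * a / (1.0 - h)
    tr_s = float(np.sum(d * (1.0 - h)))
    C = X.T @ (d[:, None] * X)
    AC = cov_unscaled @ C
    tr_s2 = float(np.sum(d * d * (1.0 - 2.0 * h)) + np.trace(AC @ AC))
    df = tr_s * tr_s / tr_s2 if tr_s2 > 0 else float(n - k)
    return np.sqrt(V), df
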