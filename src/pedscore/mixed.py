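"""Polygenic mixed models on pedigree data.

The model is y = X b + u + e with u ~ N(0, sigma_u^2 K) and
e ~ N(0, sigma_e^2 I), where K is the pedigree additive relationship
matrix. Variance components are estimated by REML after a single
eigendecomposition K = U D U': rotating by U' diagonalises the
covariance, so the restricted likelihood profile over the heritability
ratio h^2 = sigma_u^2 / (sigma_u^2 + sigma_e^2) costs O(N) per
evaluation and is maximised by bounded scalar search.

Three consumers share this machinery:

* :func:`fit_polygenic` — intercept-only fit; yields BLUP polygenic
  predictions and GRAMMAR residuals.
* :func:`measured_genotype_test` — adds one SNP as a fixed effect and
  Wald-tests it, re-estimating the variance components per SNP.
* :func:`grammar_decorrelate` — returns y - mu_hat - u_hat, the
  "decorrelated" trait treated downstream as unrelated observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .kinship import KinshipMatrix

__all__ = [
    "PolygenicFit",
    "KinshipEigen",
    "kinship_eigen",
    "adjust_covariates",
    "fit_polygenic",
    "measured_genotype_test",
    "grammar_decorrelate",
    "adjust_major_gene",
]

_H2_UPPER = 1.0 - 1e-6
_H2_XATOL = 1e-8


@dataclass(frozen=True)
class KinshipEigen:
    """Cached eigendecomposition of a kinship matrix (K = U diag(d) U')."""

    d: np.ndarray
    u: np.ndarray

    @property
    def n(self) -> int:
        return self.d.shape[0]


def kinship_eigen(k: KinshipMatrix) -> KinshipEigen:
    """Eigendecompose K once; raises if K is not numerically PSD."""
    d, u = np.linalg.eigh(k.values)
    if d.min() < -1e-8:
        raise ValueError(f"kinship matrix is not PSD (min eigenvalue {d.min():.3g})")
    return KinshipEigen(np.maximum(d, 0.0), u)


@dataclass(frozen=True)
class PolygenicFit:
    """REML fit of the intercept-only polygenic model."""

    mu_hat: float
    sigma_u2: float
    sigma_eps2: float
    h2: float
    u_hat: np.ndarray
    residuals: np.ndarray  # y - mu_hat - u_hat


def _ols_residuals(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Rank-aware least-squares residuals of y on a design with intercept."""
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def adjust_covariates(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of the trait on intercept + covariate columns.

    ``covariates`` is N x C (typically age and sex). Residuals are the
    unique projection even if a covariate column is collinear with the
    intercept.
    """
    y = np.asarray(y, dtype=float)
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != y.shape[0]:
        c = c.T
    if np.isnan(c).any():
        raise ValueError("missing covariate values are not allowed")
    design = np.column_stack([np.ones_like(y), c])
    return _ols_residuals(y, design)


def adjust_major_gene(y_star: np.ndarray, major_dosages: np.ndarray) -> np.ndarray:
    """Remove strong major-gene effects from a decorrelated trait by OLS.

    ``major_dosages`` is N x M (M >= 1 SNP dosage columns). Duplicate /
    collinear columns are tolerated; residuals stay unique.
    """
    y_star = np.asarray(y_star, dtype=float)
    g = np.asarray(major_dosages, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    if g.shape[1] < 1:
        raise ValueError("need at least one major-gene dosage column")
    design = np.column_stack([np.ones_like(y_star), g])
    return _ols_residuals(y_star, design)


def _reml_neg_loglik(h2: float, d: np.ndarray, ystar: np.ndarray, xstar: np.ndarray):
    """Negative restricted log-likelihood profile at heritability h2.

    Works in the rotated basis, with the common scale sigma_p^2
    (= sigma_u^2 + sigma_e^2) profiled out.
    """
    w = 1.0 / (h2 * d + (1.0 - h2))
    xtw = xstar.T * w
    xtwx = xtw @ xstar
    beta = np.linalg.solve(xtwx, xtw @ ystar)
    r = ystar - xstar @ beta
    rss = float(np.dot(w * r, r))
    n, p = xstar.shape
    if rss <= 0:
        raise ValueError("degenerate restricted likelihood (zero residual variance)")
    sigma_p2 = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        raise ValueError("design matrix is rank deficient in the rotated basis")
    ll = -0.5 * ((n - p) * np.log(sigma_p2) - np.log(w).sum() + logdet_xtwx + (n - p))
    return -ll, beta, sigma_p2, xtwx, r, w


def _reml_maximize(d: np.ndarray, ystar: np.ndarray, xstar: np.ndarray) -> float:
    """Maximise the REML profile over h2 in [0, 1); boundary ties give 0."""
    obj = lambda h2: _reml_neg_loglik(h2, d, ystar, xstar)[0]
    res = optimize.minimize_scalar(
        obj, bounds=(0.0, _H2_UPPER), method="bounded", options={"xatol": _H2_XATOL}
    )
    h2 = float(res.x)
    # tie-break: a flat or boundary-maximised profile returns exactly 0
    if obj(0.0) <= res.fun + 1e-9:
        return 0.0
    return h2


def fit_polygenic(
    y: np.ndarray,
    k: KinshipMatrix,
    eig: KinshipEigen | None = None,
) -> PolygenicFit:
    """REML fit of y = mu + u + e with u ~ N(0, sigma_u^2 K).

    ``eig`` may carry a precomputed eigendecomposition of K so repeated
    fits on the same pedigree (e.g. one per trait replicate) amortise
    the O(N^3) cost.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 individuals, got {n}")
    if n != k.n:
        raise ValueError("trait length does not match kinship matrix")
    if np.var(y) == 0:
        raise ValueError("trait has zero variance")
    eig = eig or kinship_eigen(k)

    ystar = eig.u.T @ y
    xstar = eig.u.T @ np.ones((n, 1))
    h2 = _reml_maximize(eig.d, ystar, xstar)
    _, beta, sigma_p2, _, r, w = _reml_neg_loglik(h2, eig.d, ystar, xstar)

    mu_hat = float(beta[0])
    sigma_u2 = h2 * sigma_p2
    sigma_eps2 = (1.0 - h2) * sigma_p2
    # BLUP: u_hat = sigma_u2 K V^-1 (y - mu) = U (h2 * d * w * r) in rotated basis
    u_hat = eig.u @ (h2 * eig.d * w * r)
    residuals = y - mu_hat - u_hat
    return PolygenicFit(mu_hat, sigma_u2, sigma_eps2, h2, u_hat, residuals)


def measured_genotype_test(
    y: np.ndarray,
    g: np.ndarray,
    k: KinshipMatrix,
    eig: KinshipEigen | None = None,
    varcomp: PolygenicFit | None = None,
) -> tuple[float, float, float]:
    """Mixed-model association test of one SNP (the measured genotype test).

    Fits y = mu + g*beta + u + e and Wald-tests beta against a standard
    normal. Variance components are re-estimated per SNP by REML unless
    ``varcomp`` supplies a null-model fit to reuse (EMMAX-style
    shortcut). Missing dosages are mean-imputed.

    Returns ``(beta, se, p)`` with p two-sided in (0, 1].
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float).copy()
    miss = ~np.isfinite(g) | (g < 0)
    if miss.any():
        g[miss] = g[~miss].mean()
    if np.unique(g).size < 2:
        raise ValueError("monomorphic SNP: dosage has fewer than 2 distinct values")
    eig = eig or kinship_eigen(k)
    n = y.shape[0]

    x = np.column_stack([np.ones(n), g])
    ystar = eig.u.T @ y
    xstar = eig.u.T @ x
    if varcomp is None:
        h2 = _reml_maximize(eig.d, ystar, xstar)
    else:
        tot = varcomp.sigma_u2 + varcomp.sigma_eps2
        h2 = varcomp.sigma_u2 / tot if tot > 0 else 0.0
    _, beta, sigma_p2, xtwx, _, _ = _reml_neg_loglik(h2, eig.d, ystar, xstar)
    cov = sigma_p2 * np.linalg.inv(xtwx)
    b = float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    z = b / se
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
    return b, se, p


def grammar_decorrelate(
    y: np.ndarray,
    k: KinshipMatrix,
    eig: KinshipEigen | None = None,
) -> np.ndarray:
    """GRAMMAR step: residuals y - mu_hat - u_hat of the polygenic fit.

    The output is treated downstream as a panel of unrelated
    observations, enabling plain linear-model scans.
    """
    return fit_polygenic(y, k, eig=eig).residuals
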