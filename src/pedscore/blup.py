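"""SNP-BLUP: simultaneous ridge estimation of all SNP effects.

All J SNP effects are treated as random, alpha ~ N(0, sigma_alpha^2 I),
and estimated jointly by penalised least squares with penalty
lambda = sigma_eps^2 / sigma_alpha^2. The per-SNP variance follows from
the total additive genetic variance VA through
VA = sum_j 2 p_j q_j sigma_alpha^2, so lambda is fully determined by
(VA, sigma_eps^2) and the allele frequencies. Fitted on 2p-centered
dosages this model is equivalent to GBLUP with the VanRaden-style
genomic relationship matrix G = sigma_alpha^2 Xc Xc'; the equivalence
is exposed by :func:`gblup_predict` and exercised in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .synthetic import MISSING, GenotypeMatrix

__all__ = [
    "BlupFit",
    "lambda_from_va",
    "fit_snp_blup",
    "gblup_predict",
    "rank_by_effect",
]


@dataclass(frozen=True)
class BlupFit:
    """Ridge (SNP-BLUP) solution and the variance bookkeeping behind it."""

    alpha_hat: np.ndarray
    lambda_: float
    sigma_alpha2: float | None
    va: float | None
    sum_2pq: float
    included_snps: list[str]
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")
        if len(self.alpha_hat) != len(self.included_snps):
            raise ValueError("alpha_hat length must match included_snps")
        if self.sigma_alpha2 is not None and self.va is not None and self.sum_2pq > 0:
            if not np.isclose(self.sigma_alpha2, self.va / self.sum_2pq, rtol=1e-12):
                raise ValueError("sigma_alpha2 must equal va / sum_2pq")

    def effects(self) -> dict[str, float]:
        return dict(zip(self.included_snps, self.alpha_hat))


def lambda_from_va(
    va: float, freqs: np.ndarray, sigma_eps2: float
) -> tuple[float, float, float]:
    """Variance-derived ridge penalty.

    sigma_alpha^2 = VA / sum_j 2 p_j q_j (monomorphic SNPs contribute
    zero) and lambda = sigma_eps^2 / sigma_alpha^2.

    Returns ``(lambda_, sigma_alpha2, sum_2pq)``.
    """
    if va <= 0:
        raise ValueError("va must be positive")
    if sigma_eps2 <= 0:
        raise ValueError("sigma_eps2 must be positive")
    p = np.asarray(freqs, dtype=float)
    sum_2pq = float(np.nansum(2.0 * p * (1.0 - p)))
    if sum_2pq <= 0:
        raise ValueError("all SNPs are monomorphic (sum 2pq = 0)")
    sigma_alpha2 = va / sum_2pq
    return sigma_eps2 / sigma_alpha2, sigma_alpha2, sum_2pq


def _centered_design(genotypes: GenotypeMatrix) -> np.ndarray:
    """Dosages centered by 2 p_j, with missing calls imputed to 2 p_j."""
    x = genotypes.dosages.astype(float)
    center = 2.0 * genotypes.freqs
    x = x - center
    x[genotypes.dosages == MISSING] = 0.0
    return x


def _solve_spd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cholesky solve with a tiny jitter retry for near-singular systems."""
    try:
        c, low = linalg.cho_factor(a, check_finite=False)
    except linalg.LinAlgError:
        a = a + 1e-10 * np.trace(a) / a.shape[0] * np.eye(a.shape[0])
        c, low = linalg.cho_factor(a, check_finite=False)
    return linalg.cho_solve((c, low), b, check_finite=False)


def fit_snp_blup(
    y_star: np.ndarray,
    genotypes: GenotypeMatrix,
    lambda_: float,
    sigma_alpha2: float | None = None,
    va: float | None = None,
) -> BlupFit:
    """Ridge solution alpha_hat = argmin ||y - Xc a||^2 + lambda ||a||^2.

    Uses the dual (N x N) form Xc'(Xc Xc' + lambda I)^-1 y when J > N
    and the primal (J x J) normal equations otherwise; the two agree to
    numerical precision. The trait is centered defensively.
    """
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    y = np.asarray(y_star, dtype=float)
    if y.shape[0] != genotypes.n:
        raise ValueError("trait length does not match genotype rows")
    y = y - y.mean()
    xc = _centered_design(genotypes)
    n, j = xc.shape
    if j > n:
        dual = _solve_spd(xc @ xc.T + lambda_ * np.eye(n), y)
        alpha = xc.T @ dual
    else:
        alpha = _solve_spd(xc.T @ xc + lambda_ * np.eye(j), xc.T @ y)
    p = genotypes.freqs
    sum_2pq = float(np.nansum(2.0 * p * (1.0 - p)))
    return BlupFit(
        alpha_hat=alpha,
        lambda_=lambda_,
        sigma_alpha2=sigma_alpha2,
        va=va,
        sum_2pq=sum_2pq,
        included_snps=genotypes.snp_ids,
        snp_map=genotypes.snp_map,
    )


def gblup_predict(
    y_star: np.ndarray,
    genotypes: GenotypeMatrix,
    sigma_alpha2: float,
    sigma_eps2: float,
) -> np.ndarray:
    """Predicted genetic values via the genomic relationship matrix.

    g_hat = G (G + sigma_eps^2 I)^-1 y with G = sigma_alpha^2 Xc Xc'.
    Identical (up to numerical precision) to Xc @ alpha_hat from
    :func:`fit_snp_blup` with lambda = sigma_eps^2 / sigma_alpha^2.
    """
    if sigma_alpha2 < 0 or sigma_eps2 <= 0:
        raise ValueError("need sigma_alpha2 >= 0 and sigma_eps2 > 0")
    y = np.asarray(y_star, dtype=float)
    y = y - y.mean()
    xc = _centered_design(genotypes)
    g = sigma_alpha2 * (xc @ xc.T)
    return g @ _solve_spd(g + sigma_eps2 * np.eye(genotypes.n), y)


def rank_by_effect(fit: BlupFit) -> list[str]:
    """SNP ids by descending |alpha_hat|; ties by (chrom, bp, snp_id)."""
    if len(fit.included_snps) == 0:
        raise ValueError("empty BLUP fit")
    t = fit.snp_map.set_index("snp_id").loc[fit.included_snps]
    frame = pd.DataFrame(
        {
            "snp_id": fit.included_snps,
            "neg_abs": -np.abs(fit.alpha_hat),
            "chromosome": t["chromosome"].to_numpy(),
            "bp_position": t["bp_position"].to_numpy(),
        }
    )
    order = frame.sort_values(
        ["neg_abs", "chromosome", "bp_position", "snp_id"], kind="mergesort"
    )
    return list(order["snp_id"])
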