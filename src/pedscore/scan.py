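"""Single-marker linear-model genome scan on a decorrelated trait.

Each SNP is tested by simple OLS of the trait on intercept + dosage,
using the closed-form correlation-based t statistic so the whole scan
is a handful of vectorised matrix operations rather than J separate
model fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic import GenotypeMatrix

__all__ = ["ScanResult", "scan", "rank_by_pvalue"]


@dataclass(frozen=True)
class ScanResult:
    """Per-SNP OLS estimates in SNP-map order.

    ``table`` columns: snp_id, chromosome, bp_position, beta, se, p,
    n_used. ``excluded`` lists SNPs dropped by the MAF filter (or
    monomorphic ones).
    """

    table: "object"  # pandas.DataFrame
    excluded: list[str]

    def pvalues(self) -> dict[str, float]:
        return dict(zip(self.table["snp_id"], self.table["p"]))

    def betas(self) -> dict[str, float]:
        return dict(zip(self.table["snp_id"], self.table["beta"]))


def scan(
    y_star: np.ndarray,
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
) -> ScanResult:
    """OLS association scan of ``y_star`` against every SNP.

    Missing dosages are mean-imputed (2 * sample allele frequency);
    SNPs with minor allele frequency below ``maf_min`` are excluded and
    reported in ``ScanResult.excluded``. Two-sided p-values come from
    the t distribution with N-2 degrees of freedom, floored at the
    smallest positive float so p stays in (0, 1].
    """
    import pandas as pd

    y = np.asarray(y_star, dtype=float)
    n = genotypes.n
    if y.shape[0] != n:
        raise ValueError("trait length does not match genotype rows")
    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")

    maf = np.minimum(genotypes.freqs, 1.0 - genotypes.freqs)
    keep = np.isfinite(maf) & (maf >= maf_min) & (maf > 0.0)
    excluded = [s for s, k in zip(genotypes.snp_ids, keep) if not k]
    if not keep.any():
        raise ValueError("every SNP was removed by the MAF filter")

    x = genotypes.imputed(np.flatnonzero(keep))
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    poly = sxx > 0
    sxx = np.where(poly, sxx, np.nan)
    sxy = xc.T @ yc
    syy = float(yc @ yc)

    beta = sxy / sxx
    rss = np.maximum(syy - beta * sxy, 0.0)
    df = n - 2
    sigma2 = rss / df
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny, 1.0)

    sub = genotypes.snp_map.loc[keep, ["snp_id", "chromosome", "bp_position"]].reset_index(drop=True)
    table = sub.assign(beta=beta, se=se, p=p, n_used=n)
    if not poly.all():
        # imputation made some kept SNPs constant: drop them too
        excluded += list(table.loc[~poly, "snp_id"])
        table = table.loc[poly].reset_index(drop=True)
    if table.empty:
        raise ValueError("every SNP was removed by the MAF filter")
    return ScanResult(table, excluded)


def rank_by_pvalue(result: ScanResult) -> list[str]:
    """SNP ids by ascending p; ties by (chromosome, bp_position, snp_id)."""
    t = result.table
    if len(t) == 0:
        raise ValueError("empty scan result")
    order = t.sort_values(
        ["p", "chromosome", "bp_position", "snp_id"], kind="mergesort"
    )
    return list(order["snp_id"])
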