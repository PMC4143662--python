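"""Discovery/replication evaluation of polygenic-score strategies.

One trait replicate serves as the discovery set: it is decorrelated
(covariate adjustment, GRAMMAR, optional major-gene adjustment) and
both rankings are computed on it — single-marker p-values and SNP-BLUP
effect magnitudes. Pruned top-S sets from each ranking are then scored
on the shared genotypes and tested for association against every other
replicate (decorrelated the same way). The replication rate of a
(strategy, S, alpha) cell is the fraction of replicates reaching
p <= alpha. Run on a null trait panel the same machinery measures
type-I error; run on within-family permutations of a real trait it
probes residual confounding by family structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .blup import BlupFit, fit_snp_blup, lambda_from_va, rank_by_effect
from .kinship import KinshipMatrix
from .mixed import (
    KinshipEigen,
    adjust_covariates,
    adjust_major_gene,
    fit_polygenic,
    kinship_eigen,
    measured_genotype_test,
)
from .scan import ScanResult, rank_by_pvalue, scan
from .score import SnpSet, compute_scores, prune_by_window, select_top
from .synthetic import GenotypeMatrix, Pedigree, TraitPanel

__all__ = [
    "Discovery",
    "ReplicationSummary",
    "decorrelate_replicate",
    "run_discovery",
    "build_snp_sets",
    "replication_rates",
    "permute_within_families",
    "type1_error",
    "power_measured_genotype",
]

#: Fraction of trait variance used as a floor for VA when a replicate's
#: REML polygenic variance is (near) zero, keeping the ridge penalty finite.
_VA_FLOOR_FRACTION = 0.01


@dataclass(frozen=True)
class ReplicationSummary:
    """Rates per (strategy, S, alpha) cell.

    ``table`` columns: strategy, S, alpha, n_replicates, n_significant,
    rate (= n_significant / n_replicates exactly).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if not np.array_equal(
            t["n_significant"].to_numpy(), (t["rate"] * t["n_replicates"]).round().astype(int)
        ):
            raise ValueError("rate must equal n_significant / n_replicates")

    def rate(self, strategy: str, s: int, alpha: float) -> float:
        t = self.table
        row = t[(t["strategy"] == strategy) & (t["S"] == s) & (t["alpha"] == alpha)]
        if len(row) != 1:
            raise KeyError(f"no unique cell ({strategy}, {s}, {alpha})")
        return float(row["rate"].iloc[0])


@dataclass(frozen=True)
class Discovery:
    """Everything estimated on the discovery replicate."""

    scan: ScanResult
    blup: BlupFit
    replicate_index: int
    y_adjusted: np.ndarray  # decorrelated (and major-gene-adjusted) trait
    va: float
    sigma_eps2: float


def decorrelate_replicate(
    panel: TraitPanel,
    r: int,
    k: KinshipMatrix,
    eig: KinshipEigen | None = None,
    major_dosages: np.ndarray | None = None,
) -> np.ndarray:
    """Covariate-adjust, GRAMMAR-decorrelate and major-gene-adjust one replicate."""
    y = adjust_covariates(panel.replicate(r), panel.covariates)
    y_star = fit_polygenic(y, k, eig=eig).residuals
    if major_dosages is not None and major_dosages.size:
        y_star = adjust_major_gene(y_star, major_dosages)
    return y_star


def _major_dosage_columns(
    genotypes: GenotypeMatrix, major_snp_ids: list[str] | None
) -> np.ndarray | None:
    if not major_snp_ids:
        return None
    return genotypes.imputed(genotypes.column_index(major_snp_ids))


def run_discovery(
    replicate_index: int,
    panel: TraitPanel,
    genotypes: GenotypeMatrix,
    k: KinshipMatrix,
    major_snp_ids: list[str] | None = None,
    maf_min: float = 0.01,
    eig: KinshipEigen | None = None,
    va: float | None = None,
    sigma_eps2: float | None = None,
) -> Discovery:
    """Decorrelate the discovery replicate, then scan and fit SNP-BLUP.

    Both rankings are computed on the identical adjusted trait. The
    ridge penalty uses VA and sigma_eps^2 from the replicate's own
    polygenic REML fit unless supplied explicitly; VA is floored at 1%
    of the adjusted-trait variance so a null trait (REML polygenic
    variance ~ 0) still yields a finite, very large penalty.
    """
    eig = eig or kinship_eigen(k)
    y_cov = adjust_covariates(panel.replicate(replicate_index), panel.covariates)
    poly = fit_polygenic(y_cov, k, eig=eig)
    y_star = poly.residuals
    major = _major_dosage_columns(genotypes, major_snp_ids)
    if major is not None:
        y_star = adjust_major_gene(y_star, major)

    if va is None:
        va = max(poly.sigma_u2, _VA_FLOOR_FRACTION * float(np.var(y_cov)))
    if sigma_eps2 is None:
        sigma_eps2 = poly.sigma_eps2

    scan_result = scan(y_star, genotypes, maf_min=maf_min)
    lam, sigma_alpha2, _ = lambda_from_va(va, genotypes.freqs, sigma_eps2)
    blup_fit = fit_snp_blup(y_star, genotypes, lam, sigma_alpha2=sigma_alpha2, va=va)
    return Discovery(scan_result, blup_fit, replicate_index, y_star, va, sigma_eps2)


def build_snp_sets(
    discovery: Discovery,
    s_grid: list[int],
    window_bp: int = 100_000,
    gw_threshold: float = 1e-8,
    strategies: tuple[str, ...] = ("single_marker", "blup"),
) -> dict[tuple[str, int], SnpSet]:
    """Pruned top-S sets for every (strategy, S) cell of the grid."""
    snp_map = discovery.blup.snp_map
    sets: dict[tuple[str, int], SnpSet] = {}
    for strategy in strategies:
        if strategy == "single_marker":
            stat = pd.Series(discovery.scan.pvalues())
            scanned_map = discovery.scan.table  # excludes MAF-filtered SNPs
            pruned = prune_by_window(scanned_map, stat, window_bp, orientation="min")
            ranking = rank_by_pvalue(discovery.scan)
            weights = discovery.scan.betas()
        elif strategy == "blup":
            stat = pd.Series(discovery.blup.effects())
            pruned = prune_by_window(snp_map, stat, window_bp, orientation="max")
            ranking = rank_by_effect(discovery.blup)
            weights = discovery.blup.effects()
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        for s in s_grid:
            sets[(strategy, s)] = select_top(
                pruned,
                ranking,
                weights,
                s,
                strategy=strategy,
                snp_map=snp_map,
                discovery_scan=discovery.scan,
                gw_threshold=gw_threshold,
                window_bp=window_bp,
                discovery_replicate=discovery.replicate_index,
            )
    return sets


def _batch_ols_pvalues(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Two-sided OLS slope p-values of each column of ``ys`` on ``x``."""
    n = x.shape[0]
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = ys - ys.mean(axis=0)
    sxy = xc @ yc
    syy = np.einsum("ij,ij->j", yc, yc)
    beta = sxy / sxx
    rss = np.maximum(syy - beta * sxy, 0.0)
    df = n - 2
    se = np.sqrt(rss / df / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    return np.clip(2.0 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny, 1.0)


def replication_rates(
    discovery: Discovery,
    panel: TraitPanel,
    genotypes: GenotypeMatrix,
    k: KinshipMatrix,
    s_grid: list[int],
    alpha_grid: list[float],
    major_snp_ids: list[str] | None = None,
    window_bp: int = 100_000,
    gw_threshold: float = 1e-8,
    strategies: tuple[str, ...] = ("single_marker", "blup"),
    eig: KinshipEigen | None = None,
) -> ReplicationSummary:
    """Replication rate per (strategy, S, alpha) over all non-discovery replicates.

    Genotypes are shared across replicates, so each SNP set's score
    vector is computed once; every remaining replicate is decorrelated
    independently and regressed on the scores.
    """
    if panel.n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if not s_grid or not alpha_grid:
        raise ValueError("S and alpha grids must be non-empty")
    eig = eig or kinship_eigen(k)
    sets = build_snp_sets(discovery, s_grid, window_bp, gw_threshold, strategies)
    score_vectors = {key: compute_scores(ss, genotypes) for key, ss in sets.items()}

    major = _major_dosage_columns(genotypes, major_snp_ids)
    reps = [r for r in range(1, panel.n_replicates + 1) if r != discovery.replicate_index]
    ys = np.column_stack(
        [decorrelate_replicate(panel, r, k, eig=eig, major_dosages=major) for r in reps]
    )

    rows = []
    for (strategy, s), sv in score_vectors.items():
        pvals = _batch_ols_pvalues(sv.ps, ys)
        for alpha in alpha_grid:
            n_sig = int((pvals <= alpha).sum())
            rows.append(
                {
                    "strategy": strategy,
                    "S": s,
                    "alpha": alpha,
                    "n_replicates": len(reps),
                    "n_significant": n_sig,
                    "rate": n_sig / len(reps),
                }
            )
    return ReplicationSummary(pd.DataFrame(rows))


def permute_within_families(
    y: np.ndarray, pedigree: Pedigree, seed: int = 0
) -> np.ndarray:
    """Permute trait values uniformly at random within each family block."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != pedigree.n:
        raise ValueError("trait length does not match pedigree")
    rng = np.random.default_rng(seed)
    out = y.copy()
    for idx in pedigree.family_blocks().values():
        out[idx] = y[idx][rng.permutation(idx.size)]
    return out


def type1_error(
    null_panel: TraitPanel,
    genotypes: GenotypeMatrix,
    k: KinshipMatrix,
    s_grid: list[int],
    alpha_grid: list[float],
    discovery_replicate: int = 1,
    window_bp: int = 100_000,
    gw_threshold: float = 1e-8,
    maf_min: float = 0.01,
    eig: KinshipEigen | None = None,
) -> ReplicationSummary:
    """Replication-rate machinery applied to a genotype-independent null trait.

    The resulting rates estimate the type-I error of the PS association
    test per (strategy, S, alpha) cell.
    """
    if null_panel.trait_kind != "null_like":
        raise ValueError("type1_error requires a null_like trait panel")
    eig = eig or kinship_eigen(k)
    discovery = run_discovery(
        discovery_replicate, null_panel, genotypes, k, maf_min=maf_min, eig=eig
    )
    return replication_rates(
        discovery,
        null_panel,
        genotypes,
        k,
        s_grid,
        alpha_grid,
        window_bp=window_bp,
        gw_threshold=gw_threshold,
        eig=eig,
    )


def power_measured_genotype(
    panel: TraitPanel,
    snp_id: str,
    genotypes: GenotypeMatrix,
    k: KinshipMatrix,
    alpha: float,
    eig: KinshipEigen | None = None,
) -> float:
    """Fraction of replicates where the measured genotype test hits p <= alpha."""
    eig = eig or kinship_eigen(k)
    g = genotypes.imputed(genotypes.column_index([snp_id]))[:, 0]
    hits = 0
    for r in range(1, panel.n_replicates + 1):
        y = adjust_covariates(panel.replicate(r), panel.covariates)
        _, _, p = measured_genotype_test(y, g, k, eig=eig)
        hits += p <= alpha
    return hits / panel.n_replicates
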