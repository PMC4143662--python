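"""Polygenic score construction and association testing.

A score set is built from a discovery ranking in three steps: (1) keep
only positionally independent SNPs — the best-ranked SNP per
non-overlapping window (100 kb by default) on each chromosome; (2) drop
genome-wide significant discovery SNPs (they would dominate the score
and are already "established" signals); (3) take the top S remaining
SNPs with their discovery effect estimates as weights. The score for
individual i is PS_i = sum_s w_s X_is, with a missing dosage imputed
from the scoring-sample allele frequency (2 p_s). Association of PS
with a (decorrelated) trait is tested by ordinary linear regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .scan import ScanResult
from .synthetic import MISSING, GenotypeMatrix

__all__ = [
    "SnpSet",
    "ScoreVector",
    "prune_by_window",
    "select_top",
    "compute_scores",
    "test_score_association",
]


@dataclass(frozen=True)
class SnpSet:
    """Ordered, weighted, positionally independent SNP subset.

    ``entries`` columns: snp_id, weight, ref_allele, chromosome,
    bp_position (in selection order). ``undersized`` flags a pruned pool
    smaller than the requested size S.
    """

    entries: pd.DataFrame
    size: int
    strategy: str
    window_bp: int
    discovery_replicate: int
    undersized: bool = False

    def __post_init__(self) -> None:
        if len(self.entries) > self.size:
            raise ValueError("more entries than the requested set size")
        if len(self.entries) < self.size and not self.undersized:
            raise ValueError("undersized set must carry the undersized flag")
        tile = (self.entries["bp_position"].to_numpy() - 1) // self.window_bp
        key = pd.DataFrame({"c": self.entries["chromosome"], "t": tile})
        if key.duplicated().any():
            raise ValueError("two entries share a pruning window")


@dataclass(frozen=True)
class ScoreVector:
    """Per-individual polygenic scores with imputation bookkeeping."""

    individual_ids: list[str]
    ps: np.ndarray
    n_missing_imputed: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.ps).all():
            raise ValueError("scores must be finite")
        if len(self.ps) != len(self.individual_ids):
            raise ValueError("score length must match individual_ids")


def prune_by_window(
    snp_map: pd.DataFrame,
    ranking_stat: Mapping[str, float] | pd.Series,
    window_bp: int = 100_000,
    orientation: str = "min",
) -> list[str]:
    """Keep the best SNP per non-overlapping positional window.

    Each chromosome is tiled into windows [w*W+1, (w+1)*W]; within a
    tile the single SNP with the smallest (``orientation="min"``, e.g. a
    p-value) or largest-magnitude (``orientation="max"``, e.g. a BLUP
    effect) statistic survives, ties broken by (bp_position, snp_id).
    Survivors are returned in SNP-map order.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if len(snp_map) == 0:
        raise ValueError("empty SNP map")
    if orientation not in ("min", "max"):
        raise ValueError("orientation must be 'min' or 'max'")
    stat = pd.Series(ranking_stat)
    missing = set(snp_map["snp_id"]) - set(stat.index)
    if missing:
        raise ValueError(f"ranking_stat missing {len(missing)} SNPs")

    frame = snp_map.loc[:, ["snp_id", "chromosome", "bp_position"]].copy()
    frame = frame.sort_values(["chromosome", "bp_position", "snp_id"], kind="mergesort")
    frame["stat"] = stat.reindex(frame["snp_id"]).to_numpy()
    if orientation == "max":
        frame["stat"] = -np.abs(frame["stat"])
    frame["tile"] = (frame["bp_position"] - 1) // window_bp
    best = (
        frame.sort_values(["stat", "bp_position", "snp_id"], kind="mergesort")
        .groupby(["chromosome", "tile"], sort=False)
        .head(1)
    )
    return list(
        best.sort_values(["chromosome", "bp_position", "snp_id"], kind="mergesort")["snp_id"]
    )


def select_top(
    pruned_ids: list[str],
    ranking: list[str],
    weights: Mapping[str, float],
    s: int,
    strategy: str,
    snp_map: pd.DataFrame,
    discovery_scan: ScanResult | None = None,
    exclude_genomewide: bool = True,
    gw_threshold: float = 1e-8,
    window_bp: int = 100_000,
    discovery_replicate: int = 1,
) -> SnpSet:
    """Top-S pruned SNPs in ranking order, with discovery weights.

    Genome-wide significant SNPs (discovery scan p < ``gw_threshold``)
    are removed first regardless of strategy — established signals
    would otherwise drive the score. If fewer than S SNPs remain the
    whole pool is returned with the ``undersized`` flag set.
    """
    if s < 1:
        raise ValueError("set size S must be >= 1")
    pruned = set(pruned_ids)
    banned: set[str] = set()
    if exclude_genomewide and discovery_scan is not None:
        pv = discovery_scan.pvalues()
        banned = {sid for sid, p in pv.items() if p < gw_threshold}
    chosen = [sid for sid in ranking if sid in pruned and sid not in banned][:s]

    meta = snp_map.set_index("snp_id")
    entries = pd.DataFrame(
        {
            "snp_id": chosen,
            "weight": [weights[sid] for sid in chosen],
            "ref_allele": meta.loc[chosen, "ref_allele"].to_numpy(),
            "chromosome": meta.loc[chosen, "chromosome"].to_numpy(),
            "bp_position": meta.loc[chosen, "bp_position"].to_numpy(),
        }
    )
    return SnpSet(
        entries=entries,
        size=s,
        strategy=strategy,
        window_bp=window_bp,
        discovery_replicate=discovery_replicate,
        undersized=len(chosen) < s,
    )


def compute_scores(snp_set: SnpSet, genotypes: GenotypeMatrix) -> ScoreVector:
    """PS_i = sum_s w_s X_is on the scoring sample.

    A dosage missing in the scoring data contributes 2 p_s w_s, with
    p_s the scoring-sample frequency of the set's reference allele. If
    the scoring data encode the other allele, the dosage is complemented
    (2 - X) before weighting.
    """
    ids = list(snp_set.entries["snp_id"])
    if not ids:
        return ScoreVector(
            list(genotypes.sample_ids),
            np.zeros(genotypes.n),
            np.zeros(genotypes.n, dtype=int),
        )
    cols = genotypes.column_index(ids)  # raises naming absent SNPs
    w = snp_set.entries["weight"].to_numpy(dtype=float)

    geno_ref = genotypes.snp_map.loc[cols, "ref_allele"].to_numpy()
    set_ref = snp_set.entries["ref_allele"].to_numpy()
    flip = geno_ref != set_ref

    raw = genotypes.dosages[:, cols].astype(float)
    miss = raw == MISSING
    x = np.where(flip, 2.0 - raw, raw)
    freq = np.where(flip, 1.0 - genotypes.freqs[cols], genotypes.freqs[cols])
    x[miss] = np.broadcast_to(2.0 * freq, x.shape)[miss]

    ps = x @ w
    return ScoreVector(list(genotypes.sample_ids), ps, miss.sum(axis=1).astype(int))


def test_score_association(
    y_star: np.ndarray, scores: ScoreVector
) -> tuple[float, float, float]:
    """OLS test of the trait on intercept + PS; returns (beta, se, p)."""
    y = np.asarray(y_star, dtype=float)
    x = np.asarray(scores.ps, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("trait and score lengths differ")
    if np.var(x) == 0:
        raise ValueError("constant polygenic score: association is undefined")
    n = y.shape[0]
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    beta = float(xc @ yc) / sxx
    rss = max(float(yc @ yc) - beta * float(xc @ yc), 0.0)
    df = n - 2
    se = float(np.sqrt(rss / df / sxx))
    if se == 0.0:  # exact fit: p underflows
        return beta, se, float(np.finfo(float).tiny)
    t = beta / se
    p = float(np.clip(2.0 * stats.t.sf(abs(t), df), np.finfo(float).tiny, 1.0))
    return beta, se, p
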