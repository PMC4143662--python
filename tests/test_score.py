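"""Polygenic scores: window pruning against a brute-force tile oracle,
top-S selection rules, score arithmetic (including imputation and
allele flipping), linearity, and the association test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pedscore import MISSING, ScanResult, ScoreVector, SnpSet, compute_scores, prune_by_window, select_top
from pedscore import test_score_association as score_association
from conftest import make_genotypes


def random_map(rng, n, n_chrom=3, max_bp=500_000):
    bp = rng.integers(1, max_bp, size=n)
    chrom = rng.integers(1, n_chrom + 1, size=n)
    order = np.lexsort((bp, chrom))
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n)],
            "chromosome": chrom[order],
            "bp_position": bp[order],
            "ref_allele": "A",
            "alt_allele": "G",
        }
    ).drop_duplicates(["chromosome", "bp_position"]).reset_index(drop=True)


def brute_force_prune(snp_map, stat, window, orientation):
    """Exhaustive per-tile argmax/argmin with the documented tie rule."""
    best = {}
    for _, row in snp_map.iterrows():
        tile = (row["chromosome"], (row["bp_position"] - 1) // window)
        s = stat[row["snp_id"]]
        key = (s if orientation == "min" else -abs(s), row["bp_position"], row["snp_id"])
        if tile not in best or key < best[tile][0]:
            best[tile] = (key, row["snp_id"])
    keep = {sid for _, sid in best.values()}
    sub = snp_map[snp_map["snp_id"].isin(keep)]
    return list(sub.sort_values(["chromosome", "bp_position", "snp_id"])["snp_id"])


class TestPruneByWindow:
    def test_single_tile_keeps_best_only(self):
        m = pd.DataFrame(
            {
                "snp_id": ["a", "b", "c"],
                "chromosome": [1, 1, 1],
                "bp_position": [10, 50_000, 99_999],
                "ref_allele": "A",
                "alt_allele": "G",
            }
        )
        assert prune_by_window(m, {"a": 0.5, "b": 0.01, "c": 0.9}) == ["b"]

    def test_tile_boundary_at_window_edge(self):
        m = pd.DataFrame(
            {
                "snp_id": ["a", "b"],
                "chromosome": [1, 1],
                "bp_position": [99_999, 100_001],
                "ref_allele": "A",
                "alt_allele": "G",
            }
        )
        assert prune_by_window(m, {"a": 0.5, "b": 0.9}) == ["a", "b"]

    @pytest.mark.parametrize("orientation", ["min", "max"])
    def test_matches_brute_force_oracle(self, orientation):
        rng = np.random.default_rng(1)
        m = random_map(rng, 1000)
        stat = {s: v for s, v in zip(m["snp_id"], rng.normal(size=len(m)))}
        got = prune_by_window(m, stat, window_bp=100_000, orientation=orientation)
        assert got == brute_force_prune(m, stat, 100_000, orientation)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_to_map_row_order(self, seed):
        rng = np.random.default_rng(seed)
        m = random_map(rng, 120)
        stat = {s: v for s, v in zip(m["snp_id"], rng.normal(size=len(m)))}
        shuffled = m.sample(frac=1.0, random_state=seed).reset_index(drop=True)
        assert prune_by_window(m, stat) == prune_by_window(shuffled, stat)


def scan_result(pvalues, snp_map):
    table = snp_map.loc[:, ["snp_id", "chromosome", "bp_position"]].copy()
    table["beta"] = 0.1
    table["se"] = 1.0
    table["p"] = [pvalues[s] for s in table["snp_id"]]
    table["n_used"] = 10
    return ScanResult(table, [])


class TestSelectTop:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.map = random_map(rng, 40, n_chrom=2, max_bp=1_000_000_000)
        self.ids = list(self.map["snp_id"])
        self.weights = {s: w for s, w in zip(self.ids, rng.normal(size=len(self.ids)))}

    def test_takes_first_s_in_ranking_order(self):
        ss = select_top(self.ids, self.ids, self.weights, 10, "single_marker", self.map)
        assert list(ss.entries["snp_id"]) == self.ids[:10]
        assert not ss.undersized
        np.testing.assert_allclose(
            ss.entries["weight"], [self.weights[s] for s in self.ids[:10]]
        )

    def test_genomewide_significant_snp_excluded(self):
        pv = {s: 0.5 for s in self.ids}
        pv[self.ids[0]] = 1e-12
        ss = select_top(
            self.ids, self.ids, self.weights, 10, "single_marker", self.map,
            discovery_scan=scan_result(pv, self.map),
        )
        assert self.ids[0] not in set(ss.entries["snp_id"])
        assert list(ss.entries["snp_id"]) == self.ids[1:11]

    def test_saturation_sets_warn_flag(self):
        ss = select_top(self.ids[:7], self.ids, self.weights, 10, "blup", self.map)
        assert len(ss.entries) == 7 and ss.undersized


class TestComputeScores:
    def test_single_snp_weighting(self):
        geno = make_genotypes(np.array([[0], [1], [2]], dtype=np.int8))
        entries = pd.DataFrame(
            {"snp_id": ["s0"], "weight": [2.0], "ref_allele": ["A"],
             "chromosome": [1], "bp_position": [1000]}
        )
        ss = SnpSet(entries, 1, "single_marker", 100_000, 1)
        sv = compute_scores(ss, geno)
        np.testing.assert_allclose(sv.ps, [0.0, 2.0, 4.0])

    def test_missing_dosage_imputed_from_frequency(self):
        # freq of observed dosages (0,1,2, miss) = 3/6 = 0.5... use (0,1,0,miss): p=1/6
        d = np.array([[0], [1], [0], [MISSING]], dtype=np.int8)
        geno = make_genotypes(d)
        assert geno.freqs[0] == pytest.approx(1 / 6)
        entries = pd.DataFrame(
            {"snp_id": ["s0"], "weight": [1.0], "ref_allele": ["A"],
             "chromosome": [1], "bp_position": [1000]}
        )
        sv = compute_scores(SnpSet(entries, 1, "blup", 100_000, 1), geno)
        assert sv.ps[3] == pytest.approx(2 * 1 / 6)
        assert sv.n_missing_imputed.tolist() == [0, 0, 0, 1]

    def test_allele_flip_complements_dosage(self):
        geno = make_genotypes(np.array([[0], [1], [2]], dtype=np.int8))
        entries = pd.DataFrame(
            {"snp_id": ["s0"], "weight": [1.0], "ref_allele": ["G"],
             "chromosome": [1], "bp_position": [1000]}
        )
        sv = compute_scores(SnpSet(entries, 1, "blup", 100_000, 1), geno)
        np.testing.assert_allclose(sv.ps, [2.0, 1.0, 0.0])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(100, 60)).astype(np.int8)
        geno = make_genotypes(d, positions=np.arange(60) * 200_000 + 1)
        chosen = rng.choice(60, size=50, replace=False)
        chosen.sort()
        w = rng.normal(size=50)
        entries = pd.DataFrame(
            {
                "snp_id": [f"s{j}" for j in chosen],
                "weight": w,
                "ref_allele": "A",
                "chromosome": 1,
                "bp_position": geno.snp_map.loc[chosen, "bp_position"].to_numpy(),
            }
        )
        sv = compute_scores(SnpSet(entries, 50, "blup", 100_000, 1), geno)
        oracle = np.zeros(100)
        for i in range(100):
            for s, weight in zip(chosen, w):
                oracle[i] += weight * d[i, s]
        np.testing.assert_allclose(sv.ps, oracle, atol=1e-12)

    def test_absent_snp_error_names_it(self):
        geno = make_genotypes(np.array([[0], [1]], dtype=np.int8))
        entries = pd.DataFrame(
            {"snp_id": ["nope"], "weight": [1.0], "ref_allele": ["A"],
             "chromosome": [1], "bp_position": [5]}
        )
        with pytest.raises(KeyError, match="nope"):
            compute_scores(SnpSet(entries, 1, "blup", 100_000, 1), geno)

    def test_scores_linear_over_disjoint_sets(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(30, 20)).astype(np.int8)
        geno = make_genotypes(d, positions=np.arange(20) * 200_000 + 1)
        w = rng.normal(size=20)

        def snpset(idx):
            entries = pd.DataFrame(
                {
                    "snp_id": [f"s{j}" for j in idx],
                    "weight": w[idx],
                    "ref_allele": "A",
                    "chromosome": 1,
                    "bp_position": geno.snp_map.loc[idx, "bp_position"].to_numpy(),
                }
            )
            return SnpSet(entries, len(idx), "blup", 100_000, 1)

        a, b = np.arange(0, 10), np.arange(10, 20)
        ps_union = compute_scores(snpset(np.arange(20)), geno).ps
        ps_sum = compute_scores(snpset(a), geno).ps + compute_scores(snpset(b), geno).ps
        np.testing.assert_allclose(ps_union, ps_sum, atol=1e-12)

    def test_equal_weights_reduce_to_allele_count(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(25, 8)).astype(np.int8)
        geno = make_genotypes(d, positions=np.arange(8) * 200_000 + 1)
        entries = pd.DataFrame(
            {
                "snp_id": [f"s{j}" for j in range(8)],
                "weight": 1.0,
                "ref_allele": "A",
                "chromosome": 1,
                "bp_position": geno.snp_map["bp_position"].to_numpy(),
            }
        )
        sv = compute_scores(SnpSet(entries, 8, "blup", 100_000, 1), geno)
        np.testing.assert_allclose(sv.ps, d.sum(axis=1))


class TestScoreAssociation:
    def test_perfect_association(self):
        rng = np.random.default_rng(6)
        ps = rng.normal(size=40)
        sv_ids = [f"i{k}" for k in range(40)]
        beta, _, p = score_association(ps, ScoreVector(sv_ids, ps, np.zeros(40, int)))
        assert beta == pytest.approx(1.0, abs=1e-10)
        assert p <= 1e-30

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(7)
        ps = rng.normal(size=8)
        y = rng.normal(size=8)
        beta, se, p = score_association(y, ScoreVector([f"i{k}" for k in range(8)], ps, np.zeros(8, int)))
        x = np.column_stack([np.ones(8), ps])
        coef = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ coef
        se_o = np.sqrt(resid @ resid / 6 * np.linalg.inv(x.T @ x)[1, 1])
        t = coef[1] / se_o
        assert beta == pytest.approx(coef[1], rel=1e-10)
        assert se == pytest.approx(se_o, rel=1e-10)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 6), rel=1e-10)

    def test_null_calibration(self):
        rng = np.random.default_rng(8)
        ps = rng.normal(size=100)
        sv = ScoreVector([f"i{k}" for k in range(100)], ps, np.zeros(100, int))
        rejections = sum(
            score_association(rng.normal(size=100), sv)[2] <= 0.05 for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_constant_score_rejected(self):
        sv = ScoreVector(["a", "b", "c"], np.ones(3), np.zeros(3, int))
        with pytest.raises(ValueError, match="constant"):
            score_association(np.array([1.0, 2.0, 3.0]), sv)
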