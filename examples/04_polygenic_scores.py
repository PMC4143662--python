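"""Build and test polygenic scores from a discovery ranking.

Prunes to one SNP per 100-kb window, removes genome-wide significant
SNPs, takes the top-S by discovery p-value, computes
PS_i = sum_s w_s X_is, and tests PS against an independent replicate.
"""

from pedscore import (
    additive_relationship,
    build_snp_sets,
    compute_scores,
    decorrelate_replicate,
    run_discovery,
    simulate_genotypes,
    simulate_pedigree,
    simulate_traits,
    test_score_association,
)

ped = simulate_pedigree(seed=11)
geno = simulate_genotypes(ped, n_snps=5000, seed=12)
panel = simulate_traits(geno, ped, n_replicates=10, seed=13)
k = additive_relationship(ped)
major = panel.truth[0]["major_snps"]

disc = run_discovery(1, panel, geno, k, major_snp_ids=major)
sets = build_snp_sets(disc, s_grid=[10, 1000])

for (strategy, s), snp_set in sets.items():
    scores = compute_scores(snp_set, geno)
    y2 = decorrelate_replicate(panel, 2, k, major_dosages=geno.imputed(geno.column_index(major)))
    beta, se, p = test_score_association(y2, scores)
    print(f"{strategy:>13} S={s:<5d} entries={len(snp_set.entries):<5d} "
          f"beta={beta:+.4f} se={se:.4f} p={p:.3g}")
# A significant p means the aggregate of weak discovery signals carries
# over to an independent replicate; large S pools more true weak effects
# (plus noise), small S is mostly noise at this sample size.
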