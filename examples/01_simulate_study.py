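"""Simulate a family study: pedigree, gene-dropped genotypes, traits.

Builds the default synthetic study (23 three-generation families,
10,000 SNPs, genotypes fixed across replicates) and prints the realized
variance architecture of the simulated blood-pressure-like trait.
"""

import numpy as np

from pedscore import simulate_genotypes, simulate_pedigree, simulate_traits

ped = simulate_pedigree(n_families=23, generations=3, offspring_per_couple=4, seed=11)
geno = simulate_genotypes(ped, n_snps=10_000, seed=12)
panel = simulate_traits(geno, ped, n_replicates=200, seed=13)

major = panel.truth[0]["major_snps"][0]
g = geno.imputed(geno.column_index([major]))[:, 0]
r2 = [np.corrcoef(panel.traits[:, r], g)[0, 1] ** 2 for r in range(panel.n_replicates)]

print(f"individuals: {ped.n} in {ped.table['family_id'].nunique()} families")
print(f"SNPs: {geno.n_snps}, allele frequencies {geno.freqs.min():.3f}-{geno.freqs.max():.3f}")
print(f"trait replicates: {panel.n_replicates} ({panel.trait_kind})")
print(f"major-gene SNP: {major}")
print(f"mean R^2 of trait on major dosage: {np.mean(r2):.4f}")
# The last number is the fraction of trait variance explained by the
# major gene, which the generator holds at 6.5% by construction.
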