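# Methods

## Study design

The package implements a discovery/replication design for polygenic-score
(PS) association in pedigree data. One trait replicate is the discovery
set: it is adjusted for covariates, decorrelated for family structure,
optionally adjusted for known major-gene SNPs, and used to rank all SNPs
two ways — single-marker p-values and SNP-BLUP effect magnitudes. Pruned
top-S sets from each ranking are scored on the (shared) genotypes and the
PS is tested by linear regression against every other replicate,
decorrelated the same way. Rates of p ≤ α per (strategy, S, α) cell are
the primary output; the same machinery applied to a genotype-independent
null trait measures type-I error, and within-family permutation of a real
trait probes residual confounding by family structure.

## Synthetic data generator

The generator emulates a replicated family study in which genotypes are
simulated once and held fixed while trait replicates vary.

* **Pedigrees.** Deterministic family shape: a founder couple, each couple
  has `offspring_per_couple` children, and in every generation but the
  last each child marries a new founder. Child sexes are the only random
  element. Defaults: 23 families × 3 generations × 4 offspring = 598
  individuals. (With this shape 20 families give 520; 23 was chosen to
  land near 600, the scale at which all default analyses are tuned to
  run in seconds.)
* **Genotypes.** Gene dropping: founder alleles are Bernoulli(p_j) with
  p_j ~ U(0.05, 0.5); every non-founder receives one uniformly chosen
  allele from each parent per SNP. Mendelian consistency therefore holds
  by construction, which is what makes the pedigree kinship matrix and
  within-family permutation meaningful. Positions are uniform over 10
  chromosomes of 100 Mb; linkage disequilibrium arises only through
  co-transmission within families — there is no background population LD
  model (see Limitations).
* **Traits.** Each replicate column is the sum of: a covariate term
  (age, sex), a major-gene term (one SNP, the one with the largest
  realized dosage variance), a weak-effect term (200 SNPs with Gaussian
  effects, fixed across replicates), a polygenic term from 1000 SNPs
  re-selected at random in every replicate, and a Gaussian residual.
  Default variance shares: major 0.065, weak 0.10, polygenic 0.15,
  covariates 0.05, residual the remainder. Every component is centered
  and rescaled so its realized variance equals its share exactly, and all
  non-major components are projected exactly orthogonal to the major
  dosage; the variance decomposition is therefore exact in every data
  set, not just in expectation — without the projection, the fixed
  weak/covariate components carry a random realized correlation with the
  major SNP that moves its apparent variance share by up to ±2 percentage
  points between generator seeds. The null trait uses the same machinery
  with all genetic shares zero. Replicate r uses child seed
  `seed + r`, so single replicates are reproducible in isolation.

What the generator does **not** emulate: population LD and haplotype
blocks, allele-frequency spectra with rare variants, genotyping error,
non-Gaussian trait noise, longitudinal measurements, X-linked loci.
Passing tests therefore demonstrate the correctness and calibration of
the machinery under clean family structure, not performance on real
cohort data — in particular, window pruning is exercised positionally but
never has to break real LD, and the inflation seen on permuted traits
here is driven purely by shared genotypes and family structure.

## Estimation details

* **Kinship.** Tabular (recursive) method, exact, O(N²), dense storage
  (families are independent blocks; N at the package's scale is ≲ 2000).
  A Monte-Carlo gene-dropping oracle cross-checks it in the tests. Note
  the classical values: full-sib mating gives an inbred diagonal of 1.25,
  half-sib mating 1.125.
* **REML.** One eigendecomposition K = U D U′ per kinship matrix (reused
  across replicates via an explicit `KinshipEigen` handle); the
  restricted likelihood is profiled over h² = σ²ᵤ/(σ²ᵤ+σ²ε) in the
  rotated basis, each evaluation O(N), maximised by bounded scalar search
  (tolerance 1e-8 on h²). Boundary tie-break: a flat or
  boundary-maximised profile returns h² = 0 exactly (so K = I collapses
  to OLS). REML rather than ML to keep variance components unbiased by
  the fixed effects.
* **Measured genotype test.** The SNP enters as a fixed effect and the
  variance components are re-estimated per SNP (an EMMAX-style reuse of
  the null-model components is available via the `varcomp` argument).
  Wald test with a normal reference; at the package's default N≈600 the
  difference from a t reference is negligible and the pooled type-I error
  is inside [0.04, 0.06] (verified in the acceptance tests). Missing
  dosages are mean-imputed so N stays constant.
* **Single-marker scan.** Closed-form per-SNP OLS on the decorrelated
  trait (correlation-based t statistic, N−2 df), vectorised across SNPs.
  MAF filter default 0.01, configurable; SNPs it removes are reported,
  not silently dropped.
* **SNP-BLUP.** Dosages centered by 2p_j (VanRaden-style; missing calls
  impute to 2p_j, i.e. 0 after centering), trait centered defensively.
  Dual (N×N) solve when J > N, primal (J×J) otherwise; Cholesky with a
  1e-10-scaled jitter retry. The penalty is λ = σ²ε/σ²α with
  σ²α = V_A / Σ 2p_jq_j. V_A and σ²ε default to the REML fit of the same
  replicate (V_A = σ̂²ᵤ, σ²ε = σ̂²ε); both are overridable. For a null
  trait σ̂²ᵤ can be ~0, so V_A is floored at 1% of the adjusted-trait
  variance — this only makes the already-huge penalty finite and does not
  affect traits with real polygenic signal. BLUP is fitted on the same
  decorrelated, major-gene-adjusted trait as the scan so the two
  strategies are compared on identical inputs.
* **Pruning and selection.** "Independent SNPs" is operationalised purely
  positionally: each chromosome is tiled into fixed non-overlapping
  100-kb windows [wW+1, (w+1)W] and the best SNP per tile survives (ties
  by position then id). The wording "best SNP over a window ... until the
  map was covered" could also be read as greedy selection around each top
  SNP; fixed tiling was chosen as the simpler, order-independent reading
  and is what the brute-force oracle checks. Genome-wide significant
  discovery SNPs (p < 1e-8 in the single-marker scan) are removed before
  top-S selection under **both** strategies, since established signals
  would otherwise dominate the score.
* **Scores.** PSᵢ = Σ γ̂ₛXᵢₛ implemented literally (no per-allele
  averaging); association p-values are invariant to positive rescaling of
  PS, so this convention does not affect any rate. Missing dosages impute
  to 2p̂ₛ from the scoring sample; if the scoring data encode the other
  allele the dosage is complemented to 2−X.
* **Evaluation.** Every replication replicate is decorrelated
  independently (variance components re-estimated per replicate). Score
  vectors depend only on the fixed genotypes, so they are computed once
  per (strategy, S) cell. No multiple-testing adjustment is applied
  across the (strategy, S, α) grid: the rates reported are raw nominal
  rates by design. Within-family permutation shuffles trait values
  uniformly within each family block, preserving each family's multiset
  of values exactly.

## Numerical and interface choices

* Determinism: identical seeds give bit-identical generator output and
  byte-identical analysis TSVs (stable column order, `%.10g` floats,
  POSIX newlines).
* PLINK 1 binary is the genotype interchange format (variant-major only;
  the rare sample-major mode byte is rejected rather than half-supported).
  Coordinates are 1-based inclusive.
* p-values are floored at the smallest positive float so they remain in
  (0, 1] even when a fit is exact.
* Degenerate inputs: monomorphic SNPs are rejected by the measured
  genotype test and filtered by the scan; constant polygenic scores are
  an error in the association test; collinear covariate or major-gene
  columns fall back to a rank-aware least-squares projection.

## Default problem sizes

Analyses and tests run at N = 598, J = 10,000, with 200 trait replicates
(1,000 for null-trait calibration) — large enough for stable rates and
REML estimates, small enough that the full test suite and the acceptance
script each run in well under a minute on one CPU. These are the
package's chosen desk-scale study conditions, not estimates of any
particular cohort's size.

## Known limitations

* GRAMMAR residuals are known to be slightly conservative for
  single-marker effect sizes; here they are used for ranking and for PS
  testing, where calibration on the null trait is verified empirically
  (rates at p = 0.05 fall between ~3% and ~6% per cell).
* The measured genotype test uses a Wald/normal approximation; exact
  small-sample reference distributions are out of scope.
* r²-based clumping, Bayesian effect-size models, dominance, multi-trait
  models and X-chromosome inheritance are out of scope.
* The PS weights come from a single discovery replicate; no
  cross-validation or shrinkage of the score itself is performed.
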