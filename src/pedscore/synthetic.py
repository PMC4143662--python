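"""Synthetic family studies for polygenic-score method development.

Emulates the structure of a multigeneration pedigree simulation study:
genotypes are produced once by gene dropping (explicit Mendelian
transmission of founder alleles) and held fixed across all trait
replicates, while each trait replicate combines

* a fixed major-gene term (default 6.5% of trait variance),
* a fixed set of many weak-effect causal SNPs (default 200 SNPs
  sharing 10% of the variance),
* a polygenic term built from SNPs re-selected at random in every
  replicate (default 1000 SNPs, 15%),
* age and sex covariate effects, and
* a Gaussian residual.

A null trait (independent of every genotype) is produced by the same
machinery with all genetic shares set to zero; it plays the role of a
negative control for type-I-error evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "Pedigree",
    "GenotypeMatrix",
    "TraitConfig",
    "TraitPanel",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_traits",
    "mask_missing",
]

#: Sentinel for a missing dosage in :class:`GenotypeMatrix`.
MISSING = -1

_PED_COLUMNS = ["individual_id", "family_id", "father_id", "mother_id", "sex"]


@dataclass(frozen=True)
class Pedigree:
    """Pedigree records; missing parents are coded ``"0"`` (founder).

    The table holds one row per individual with columns
    ``individual_id, family_id, father_id, mother_id, sex`` (1=male,
    2=female). Either both parents are present or both are missing, and
    the parent graph is acyclic.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing_cols = [c for c in _PED_COLUMNS if c not in t.columns]
        if missing_cols:
            raise ValueError(f"pedigree table missing columns {missing_cols}")
        object.__setattr__(self, "table", t.loc[:, _PED_COLUMNS].reset_index(drop=True))
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self.table["individual_id"])

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def founder_mask(self) -> np.ndarray:
        return (self.table["father_id"] == "0").to_numpy()

    def family_blocks(self) -> dict[str, np.ndarray]:
        """Row indices grouped by family id, in table order."""
        return {
            fam: idx.to_numpy()
            for fam, idx in self.table.groupby("family_id", sort=False).groups.items()
        }

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row index of father and mother per individual; -1 for founders."""
        pos = {iid: i for i, iid in enumerate(self.table["individual_id"])}
        father = np.array([pos.get(f, -1) for f in self.table["father_id"]], dtype=int)
        mother = np.array([pos.get(m, -1) for m in self.table["mother_id"]], dtype=int)
        return father, mother

    def topological_order(self) -> np.ndarray:
        """Row indices ordered parents-before-children.

        Raises ``ValueError`` if the parent graph has a cycle.
        """
        father, mother = self.parent_indices()
        n = self.n
        depth = np.full(n, -1, dtype=int)
        depth[self.founder_mask] = 0
        for _ in range(n + 1):
            pending = depth < 0
            if not pending.any():
                break
            ready = pending & (depth[father] >= 0) & (depth[mother] >= 0)
            if not ready.any():
                raise ValueError("pedigree parent graph has a cycle")
            depth[ready] = np.maximum(depth[father[ready]], depth[mother[ready]]) + 1
        return np.argsort(depth, kind="stable")

    def validate(self) -> None:
        t = self.table
        if t["individual_id"].duplicated().any():
            dup = t.loc[t["individual_id"].duplicated(), "individual_id"].tolist()
            raise ValueError(f"duplicate individual ids: {dup}")
        has_f = t["father_id"] != "0"
        has_m = t["mother_id"] != "0"
        if (has_f != has_m).any():
            raise ValueError("individuals must have both parents or neither")
        known = set(t["individual_id"])
        for col, want_sex in (("father_id", 1), ("mother_id", 2)):
            refs = t.loc[t[col] != "0", col]
            unknown = sorted(set(refs) - known)
            if unknown:
                raise ValueError(f"{col} references unknown individuals: {unknown}")
            sex_of = dict(zip(t["individual_id"], t["sex"]))
            bad = [r for r in refs if sex_of[r] != want_sex]
            if bad:
                raise ValueError(f"{col} individuals with wrong sex: {sorted(set(bad))}")
        if not t["sex"].isin([1, 2]).all():
            raise ValueError("sex must be 1 (male) or 2 (female)")
        self.topological_order()  # raises on cycles


@dataclass(frozen=True)
class GenotypeMatrix:
    """Additive dosages (count of the reference allele) with SNP metadata.

    ``dosages`` is N x J int8 in {0, 1, 2} with :data:`MISSING` for a
    missing call. ``snp_map`` has one row per SNP with columns
    ``snp_id, chromosome, bp_position, ref_allele, alt_allele`` sorted by
    (chromosome, bp_position). ``freqs`` is the reference-allele
    frequency per SNP computed over non-missing samples.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: list[str]
    freqs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages)
        if d.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if d.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match dosage rows")
        if d.shape[1] != len(self.snp_map):
            raise ValueError("snp_map length does not match dosage columns")
        sm = self.snp_map.reset_index(drop=True)
        order = np.lexsort((sm["bp_position"].to_numpy(), sm["chromosome"].to_numpy()))
        if not np.array_equal(order, np.arange(len(sm))):
            raise ValueError("snp_map must be sorted by (chromosome, bp_position)")
        object.__setattr__(self, "snp_map", sm)
        object.__setattr__(self, "dosages", d.astype(np.int8, copy=False))
        object.__setattr__(self, "freqs", compute_freqs(d))

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_map["snp_id"])

    def column_index(self, snp_ids) -> np.ndarray:
        pos = {sid: j for j, sid in enumerate(self.snp_map["snp_id"])}
        missing = [s for s in snp_ids if s not in pos]
        if missing:
            raise KeyError(f"SNPs absent from genotypes: {missing}")
        return np.array([pos[s] for s in snp_ids], dtype=int)

    def imputed(self, columns: np.ndarray | None = None) -> np.ndarray:
        """Float dosages with missing calls imputed to 2 * sample frequency."""
        cols = slice(None) if columns is None else columns
        x = self.dosages[:, cols].astype(float)
        fill = 2.0 * self.freqs[cols]
        miss = x == MISSING
        if miss.any():
            x[miss] = np.broadcast_to(fill, x.shape)[miss]
        return x


def compute_freqs(dosages: np.ndarray) -> np.ndarray:
    """Reference-allele frequency per SNP over non-missing samples."""
    d = np.asarray(dosages, dtype=float)
    obs = d != MISSING
    with np.errstate(invalid="ignore"):
        f = np.where(
            obs.any(axis=0),
            np.sum(np.where(obs, d, 0.0), axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1)),
            np.nan,
        )
    return f


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(
    n_families: int = 23,
    generations: int = 3,
    offspring_per_couple: int = 4,
    seed: int = 0,
) -> Pedigree:
    """Simulate disjoint multigeneration families.

    Each family starts from one founder couple. Every couple has
    ``offspring_per_couple`` children; in every generation except the
    last, each child marries a new founder of the opposite sex and the
    pair becomes a couple of the next generation. Child sexes are
    random (seeded); the family shape itself is deterministic, so e.g.
    the defaults (23 families, 3 generations, 4 offspring) give
    23 x (2 + 8 + 16) = 598 individuals.
    """
    if n_families < 1 or generations < 2 or offspring_per_couple < 1:
        raise ValueError(
            "need n_families >= 1, generations >= 2, offspring_per_couple >= 1; got "
            f"({n_families}, {generations}, {offspring_per_couple})"
        )
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str, str, int]] = []
    for f in range(1, n_families + 1):
        fam = f"fam{f:03d}"
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{fam}_i{counter:03d}"

        dad, mom = new_id(), new_id()
        rows.append((dad, fam, "0", "0", 1))
        rows.append((mom, fam, "0", "0", 2))
        couples = [(dad, mom)]
        for g in range(2, generations + 1):
            next_couples = []
            for cf, cm in couples:
                for _ in range(offspring_per_couple):
                    child = new_id()
                    sex = int(rng.integers(1, 3))
                    rows.append((child, fam, cf, cm, sex))
                    if g < generations:
                        spouse = new_id()
                        spouse_sex = 3 - sex
                        rows.append((spouse, fam, "0", "0", spouse_sex))
                        pair = (child, spouse) if sex == 1 else (spouse, child)
                        next_couples.append(pair)
            couples = next_couples
    table = pd.DataFrame(rows, columns=_PED_COLUMNS)
    return Pedigree(table)


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def simulate_genotypes(
    pedigree: Pedigree,
    n_snps: int = 10_000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_chromosomes: int = 10,
    chrom_length_bp: int = 100_000_000,
    seed: int = 0,
) -> GenotypeMatrix:
    """Gene-drop genotypes down a pedigree.

    Founder alleles are Bernoulli(p_j) with p_j ~ Uniform(maf_range);
    every non-founder receives one uniformly chosen allele from each
    parent, per SNP, so Mendelian consistency holds by construction.
    SNP positions are uniform over ``n_chromosomes`` chromosomes of
    ``chrom_length_bp`` base pairs and the map is sorted by position.
    """
    if pedigree.n == 0:
        raise ValueError("empty pedigree")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie in (0, 0.5], got {maf_range}")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)

    p = rng.uniform(lo, hi, size=n_snps)
    chrom = rng.integers(1, n_chromosomes + 1, size=n_snps)
    bp = rng.integers(1, chrom_length_bp + 1, size=n_snps)
    # resolve rare position collisions so (chrom, bp) is unique
    while True:
        key = chrom.astype(np.int64) * (chrom_length_bp + 1) + bp
        _, first = np.unique(key, return_index=True)
        dup = np.setdiff1d(np.arange(n_snps), first)
        if dup.size == 0:
            break
        bp[dup] = rng.integers(1, chrom_length_bp + 1, size=dup.size)

    order = np.lexsort((bp, chrom))
    p, chrom, bp = p[order], chrom[order], bp[order]

    n = pedigree.n
    a1 = np.zeros((n, n_snps), dtype=np.int8)
    a2 = np.zeros((n, n_snps), dtype=np.int8)
    father, mother = pedigree.parent_indices()
    topo = pedigree.topological_order()
    for i in topo:
        if father[i] < 0:
            a1[i] = rng.random(n_snps) < p
            a2[i] = rng.random(n_snps) < p
        else:
            pick_f = rng.random(n_snps) < 0.5
            pick_m = rng.random(n_snps) < 0.5
            a1[i] = np.where(pick_f, a1[father[i]], a2[father[i]])
            a2[i] = np.where(pick_m, a1[mother[i]], a2[mother[i]])

    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{c}_{b}" for c, b in zip(chrom, bp)],
            "chromosome": chrom.astype(int),
            "bp_position": bp.astype(np.int64),
            "ref_allele": "A",
            "alt_allele": "G",
        }
    )
    return GenotypeMatrix(a1 + a2, snp_map, pedigree.ids)


def mask_missing(genotypes: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Return a copy with dosages masked missing completely at random."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    d = genotypes.dosages.copy()
    d[rng.random(d.shape) < rate] = MISSING
    return GenotypeMatrix(d, genotypes.snp_map, genotypes.sample_ids)


# ---------------------------------------------------------------------------
# Trait simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitConfig:
    """Variance architecture of a simulated trait.

    All shares are fractions of the total trait variance (which is 1 by
    construction): each component is rescaled so its realized variance
    equals its share exactly, making the decomposition reproducible at
    any sample size. The major-gene and weak-effect terms are fixed
    across replicates; the polygenic SNP set is re-drawn per replicate;
    the residual is fresh Gaussian noise per replicate.
    """

    major_share: float = 0.065
    n_weak: int = 200
    weak_share: float = 0.10
    n_polygenic: int = 1000
    polygenic_share: float = 0.15
    covariate_share: float = 0.05

    def __post_init__(self) -> None:
        shares = (self.major_share, self.weak_share, self.polygenic_share, self.covariate_share)
        if any(s < 0 for s in shares):
            raise ValueError("variance shares must be non-negative")
        if sum(shares) > 1.0:
            raise ValueError(f"variance shares sum to {sum(shares):.3f} > 1")

    @property
    def residual_share(self) -> float:
        return 1.0 - (
            self.major_share + self.weak_share + self.polygenic_share + self.covariate_share
        )

    def null(self) -> "TraitConfig":
        """The same configuration with every genetic share set to zero."""
        return replace(self, major_share=0.0, weak_share=0.0, polygenic_share=0.0)


@dataclass(frozen=True)
class TraitPanel:
    """N x R replicate trait matrix with covariates and generator truth."""

    individual_ids: list[str]
    age: np.ndarray
    sex: np.ndarray
    traits: np.ndarray  # N x R
    trait_kind: str  # "dbp_like" | "null_like"
    truth: list[dict]  # one record per replicate

    def __post_init__(self) -> None:
        if self.traits.ndim != 2 or self.traits.shape[1] < 2:
            raise ValueError("traits must be N x R with R >= 2")
        if self.traits.shape[0] != len(self.individual_ids):
            raise ValueError("trait rows must match individual_ids")
        if np.isnan(self.traits).any():
            raise ValueError("missing trait values are not allowed")
        if self.trait_kind not in ("dbp_like", "null_like"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")
        if self.trait_kind == "null_like" and any(t["causal_snps"] for t in self.truth):
            raise ValueError("null_like panel must have no causal SNPs in truth")

    @property
    def n_replicates(self) -> int:
        return self.traits.shape[1]

    @property
    def covariates(self) -> np.ndarray:
        return np.column_stack([self.age, self.sex.astype(float)])

    def replicate(self, r: int) -> np.ndarray:
        """Trait column for replicate ``r`` (1-based, as in study notation)."""
        if not 1 <= r <= self.n_replicates:
            raise IndexError(f"replicate {r} out of 1..{self.n_replicates}")
        return self.traits[:, r - 1].copy()


def _scaled(v: np.ndarray, share: float) -> np.ndarray:
    """Center ``v`` and rescale so its realized variance equals ``share``."""
    c = v - v.mean()
    sd = c.std()
    if sd == 0:
        raise ValueError("cannot scale a constant component to positive variance")
    return c * (np.sqrt(share) / sd)


def simulate_traits(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    config: TraitConfig | None = None,
    n_replicates: int = 200,
    seed: int = 0,
) -> TraitPanel:
    """Simulate replicate traits on a fixed genotype panel.

    The major-gene SNP is the polymorphic SNP with the largest realized
    dosage variance (a deterministic choice); weak-effect SNPs are a
    fixed seeded draw with Gaussian effects; the per-replicate polygenic
    term uses ``config.n_polygenic`` SNPs re-sampled without replacement
    in every replicate, excluding the major and weak SNPs. Replicate r
    uses child seed ``seed + r`` so single replicates are reproducible.
    """
    config = config or TraitConfig()
    if n_replicates < 2:
        raise ValueError("need n_replicates >= 2")
    if genotypes.sample_ids != pedigree.ids:
        raise ValueError("genotype sample order must match pedigree order")
    n, j = genotypes.n, genotypes.n_snps
    base = np.random.default_rng(seed)

    dos = genotypes.imputed()
    var_g = dos.var(axis=0)

    major_ids: list[str] = []
    major_term = np.zeros(n)
    if config.major_share > 0:
        major_j = int(np.argmax(var_g))
        major_ids = [genotypes.snp_map.loc[major_j, "snp_id"]]
        major_term = _scaled(dos[:, major_j], config.major_share)
    else:
        major_j = -1

    # every non-major component is made exactly orthogonal to the major
    # dosage before scaling, so the major gene's realized variance share
    # (and the R^2 of trait-on-dosage) equals its configured share
    if config.major_share > 0:
        gm = dos[:, major_j] - dos[:, major_j].mean()
        gm_norm2 = float(gm @ gm)

        def _orth(v: np.ndarray) -> np.ndarray:
            return v - gm * (float(gm @ v) / gm_norm2)
    else:

        def _orth(v: np.ndarray) -> np.ndarray:
            return v

    age = base.uniform(20.0, 80.0, size=n)
    sex = pedigree.table["sex"].to_numpy()
    cov_raw = 0.05 * age + 0.5 * sex.astype(float)
    cov_term = (
        _scaled(_orth(cov_raw - cov_raw.mean()), config.covariate_share)
        if config.covariate_share > 0
        else np.zeros(n)
    )

    weak_idx = np.array([], dtype=int)
    weak_term = np.zeros(n)
    weak_effects = np.array([])
    if config.weak_share > 0 and config.n_weak > 0:
        pool = np.setdiff1d(np.arange(j), [major_j])
        if pool.size == 0:
            raise ValueError("no SNPs left for weak effects")
        # on very small panels leave at least half the pool for the
        # per-replicate polygenic draw
        n_weak = min(config.n_weak, max(pool.size // 2, 1))
        weak_idx = np.sort(base.choice(pool, size=n_weak, replace=False))
        weak_effects = base.normal(size=weak_idx.size)
        weak_term = _scaled(_orth(dos[:, weak_idx] @ weak_effects), config.weak_share)

    fixed_part = cov_term + major_term + weak_term
    reserved = np.concatenate(([major_j] if major_j >= 0 else [], weak_idx)).astype(int)
    poly_pool = np.setdiff1d(np.arange(j), reserved)

    traits = np.empty((n, n_replicates))
    truth: list[dict] = []
    snp_ids = np.asarray(genotypes.snp_ids)
    for r in range(1, n_replicates + 1):
        rng = np.random.default_rng(seed + r)
        poly_idx = np.array([], dtype=int)
        poly_term = np.zeros(n)
        if config.polygenic_share > 0 and config.n_polygenic > 0:
            if poly_pool.size == 0:
                raise ValueError("no SNPs left for the polygenic component")
            poly_idx = np.sort(
                rng.choice(poly_pool, size=min(config.n_polygenic, poly_pool.size), replace=False)
            )
            poly_term = _scaled(_orth(dos[:, poly_idx] @ rng.normal(size=poly_idx.size)),
                                config.polygenic_share)
        resid = (
            _scaled(_orth(rng.normal(size=n)), config.residual_share)
            if config.residual_share > 0
            else np.zeros(n)
        )
        traits[:, r - 1] = fixed_part + poly_term + resid
        causal = list(major_ids) + list(snp_ids[weak_idx]) + list(snp_ids[poly_idx])
        truth.append(
            {
                "replicate": r,
                "causal_snps": causal,
                "major_snps": list(major_ids),
                "weak_snps": list(snp_ids[weak_idx]),
                "weak_effects": weak_effects.tolist(),
                "polygenic_snps": list(snp_ids[poly_idx]),
                "shares": {
                    "major": config.major_share,
                    "weak": config.weak_share,
                    "polygenic": config.polygenic_share,
                    "covariate": config.covariate_share,
                    "residual": config.residual_share,
                },
            }
        )
    kind = "dbp_like" if (config.major_share + config.weak_share + config.polygenic_share) > 0 else "null_like"
    return TraitPanel(pedigree.ids, age, sex, traits, kind, truth)
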