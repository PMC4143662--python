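import numpy as np
import pandas as pd
import pytest

from pedscore import (
    GenotypeMatrix,
    Pedigree,
    additive_relationship,
    kinship_eigen,
    simulate_genotypes,
    simulate_pedigree,
    simulate_traits,
)


def make_pedigree(rows):
    """Pedigree from (id, fam, father, mother, sex) tuples."""
    return Pedigree(
        pd.DataFrame(rows, columns=["individual_id", "family_id", "father_id", "mother_id", "sex"])
    )


def make_genotypes(dosages, positions=None, chromosomes=None, ids=None):
    """GenotypeMatrix from a plain dosage array (rows = individuals)."""
    d = np.asarray(dosages, dtype=np.int8)
    n, j = d.shape
    bp = positions if positions is not None else np.arange(1, j + 1) * 1000
    chrom = chromosomes if chromosomes is not None else np.ones(j, dtype=int)
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(j)],
            "chromosome": chrom,
            "bp_position": bp,
            "ref_allele": "A",
            "alt_allele": "G",
        }
    )
    sample_ids = ids if ids is not None else [f"i{i}" for i in range(n)]
    return GenotypeMatrix(d, snp_map, sample_ids)


@pytest.fixture
def trio():
    """Father, mother, child."""
    return make_pedigree(
        [
            ("dad", "f1", "0", "0", 1),
            ("mom", "f1", "0", "0", 2),
            ("kid", "f1", "dad", "mom", 1),
        ]
    )


@pytest.fixture
def sib_pedigree():
    """Two founders, two full sibs, and an inbred child of the sibs."""
    return make_pedigree(
        [
            ("dad", "f1", "0", "0", 1),
            ("mom", "f1", "0", "0", 2),
            ("bro", "f1", "dad", "mom", 1),
            ("sis", "f1", "dad", "mom", 2),
            ("inb", "f1", "bro", "sis", 1),
        ]
    )


@pytest.fixture(scope="session")
def mid_study():
    """Shared medium study: 598 individuals, 2000 SNPs, 30 replicates."""
    ped = simulate_pedigree(seed=101)
    geno = simulate_genotypes(ped, n_snps=2000, seed=102)
    k = additive_relationship(ped)
    eig = kinship_eigen(k)
    panel = simulate_traits(geno, ped, n_replicates=30, seed=103)
    return ped, geno, k, eig, panel
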