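import numpy as np
import pytest

from epistasiskit import GenotypeMatrix


def make_gm(genotypes, phenotype, snp_names=None, allele_labels=None):
    genotypes = np.asarray(genotypes)
    n, m = genotypes.shape
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n)],
        phenotype=np.asarray(phenotype),
        snp_names=snp_names or [f"snp{j}" for j in range(m)],
        genotypes=genotypes,
        allele_labels=allele_labels or {},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_gm():
    """8 subjects x 2 SNPs, both classes present, one missing value."""
    geno = [[0, 1], [1, 2], [2, 0], [0, 0], [1, 1], [2, 2], [0, -1], [1, 0]]
    pheno = [1, 1, 1, 0, 0, 0, 0, 0]
    return make_gm(geno, pheno, snp_names=["rsA", "rsB"])


def random_table(rng, n_rows=2, n_cols=3, n_min=1, n_max=40):
    """Random non-degenerate contingency counts."""
    while True:
        t = rng.integers(n_min, n_max, size=(n_rows, n_cols))
        if (t.sum(axis=0) > 0).all() and (t.sum(axis=1) > 0).all():
            return t


def counts_to_attrs(table):
    """Expand a (classes x categories) count table into label vectors."""
    cls, cat = [], []
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            cls.extend([i] * int(table[i, j]))
            cat.extend([j] * int(table[i, j]))
    return np.array(cls), np.array(cat)
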