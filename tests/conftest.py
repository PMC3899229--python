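import numpy as np
import pytest

from hybridkit.core import (MISSING, GenotypeMatrix, IndividualMeta, Locus)


def make_matrix(genotypes, groups, locus_alleles=None, ids=None, popflags=None):
    """Build a GenotypeMatrix from a nested list
    genotypes[individual][locus] = (a, b) with None for missing copies."""
    calls = np.array([
        [[MISSING if c is None else c for c in pair] for pair in row]
        for row in genotypes
    ], dtype=np.int64)
    n, L = calls.shape[0], calls.shape[1]
    if locus_alleles is None:
        locus_alleles = []
        for j in range(L):
            copies = calls[:, j, :].ravel()
            locus_alleles.append(tuple(sorted(set(copies[copies != MISSING].tolist()))))
    loci = [Locus(f"loc{j+1}", tuple(locus_alleles[j])) for j in range(L)]
    ids = ids or [f"ind{i+1}" for i in range(n)]
    popflags = popflags or [False] * n
    individuals = [IndividualMeta(id=i, group=g, popflag=f)
                   for i, g, f in zip(ids, groups, popflags)]
    return GenotypeMatrix(individuals, loci, calls)


@pytest.fixture
def two_group_toy():
    """Two groups of two diploids at two loci; group A carries allele 7
    privately at locus 2."""
    return make_matrix(
        [
            [(1, 1), (7, 2)],
            [(1, 2), (2, 2)],
            [(2, 2), (2, 2)],
            [(1, 2), (2, 3)],
        ],
        groups=["A", "A", "B", "B"],
    )


@pytest.fixture
def diagnostic_pair():
    """Two groups fixed for different alleles at every locus."""
    genos_a = [[(1, 1)] * 3 for _ in range(6)]
    genos_b = [[(2, 2)] * 3 for _ in range(6)]
    return make_matrix(genos_a + genos_b, groups=["A"] * 6 + ["B"] * 6)


@pytest.fixture(scope="session")
def parental_pops():
    """Session-scoped synthetic parental populations at the default study
    conditions (39 loci, theta ~ 0.25, Ho 0.46 / 0.71, 60 + 60)."""
    from hybridkit.simulate import SyntheticPopSpec, simulate_parental_pops

    return simulate_parental_pops(SyntheticPopSpec(seed=11))
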