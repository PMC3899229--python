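import numpy as np
import pytest

from hybridkit.core import MISSING
from hybridkit.differentiation import (allele_count_distances, amova_phipt,
                                       mismatch_distances,
                                       weir_cockerham_theta)
from hybridkit.fixtures import haplotype_counts

from conftest import make_matrix


def oracle_theta(pop_calls):
    """Independently coded variance-components estimator for one locus.

    ``pop_calls``: list of (n_i, 2) genotype arrays. Follows the published
    per-allele component algebra with explicit python loops, no shortcuts.
    """
    alleles = sorted({int(a) for calls in pop_calls for a in calls.ravel()})
    r = len(pop_calls)
    n = [c.shape[0] for c in pop_calls]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    A = B = C = 0.0
    for allele in alleles:
        p = []
        h = []
        for calls in pop_calls:
            count = sum(int(a == allele) for row in calls for a in row)
            p.append(count / (2 * calls.shape[0]))
            hets = sum(1 for row in calls
                       if row[0] != row[1] and allele in (row[0], row[1]))
            h.append(hets / calls.shape[0])
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        A += a
        B += b
        C += hbar / 2
    return A / (A + B + C)


class TestWeirCockerham:
    def test_fixed_difference_gives_one(self, diagnostic_pair):
        assert weir_cockerham_theta(diagnostic_pair, ["A", "B"]) == pytest.approx(1.0)

    def test_identical_groups_near_zero(self):
        rows = [[(1, 2), (2, 3)], [(1, 1), (3, 3)], [(2, 2), (2, 3)]]
        gm = make_matrix(rows + rows, ["A"] * 3 + ["B"] * 3,
                         ids=[f"i{k}" for k in range(6)])
        assert weir_cockerham_theta(gm, ["A", "B"]) <= 0.01

    def test_matches_bruteforce_oracle_on_spec_example(self):
        # two demes of 10 diploids; allele-1 counts 15/20 vs 5/20
        rng = np.random.default_rng(0)

        def deme(n_allele1):
            copies = [1] * n_allele1 + [2] * (20 - n_allele1)
            rng.shuffle(copies)
            return np.array(copies).reshape(10, 2)

        d1, d2 = deme(15), deme(5)
        genos = [[tuple(row)] for row in np.concatenate([d1, d2])]
        gm = make_matrix(genos, ["A"] * 10 + ["B"] * 10,
                         ids=[f"i{k}" for k in range(20)])
        ours = weir_cockerham_theta(gm, ["A", "B"])
        assert ours == pytest.approx(oracle_theta([d1, d2]), abs=1e-12)

    def test_matches_oracle_multilocus_multiallelic(self):
        rng = np.random.default_rng(42)
        L = 4
        popA = rng.integers(1, 5, size=(8, L, 2))
        popB = rng.integers(2, 7, size=(12, L, 2))
        genos = [[tuple(ind[j]) for j in range(L)]
                 for ind in np.concatenate([popA, popB])]
        gm = make_matrix(genos, ["A"] * 8 + ["B"] * 12,
                         ids=[f"i{k}" for k in range(20)])
        ours_per_locus = weir_cockerham_theta(gm, ["A", "B"], scope="per_locus")
        for j in range(L):
            want = oracle_theta([popA[:, j, :], popB[:, j, :]])
            assert ours_per_locus[f"loc{j+1}"] == pytest.approx(want, abs=1e-12)

    def test_balding_nichols_recovers_known_fst(self):
        # two demes drawn with drift F = 0.25: the estimator should recover it
        rng = np.random.default_rng(9)
        F, L, n = 0.25, 100, 60
        scale = (1 - F) / F
        genos_a, genos_b = [], []
        p_anc = rng.dirichlet(np.ones(8), size=L)
        for j in range(L):
            pa = rng.dirichlet(p_anc[j] * scale)
            pb = rng.dirichlet(p_anc[j] * scale)
            genos_a.append(rng.choice(8, size=(n, 2), p=pa) + 1)
            genos_b.append(rng.choice(8, size=(n, 2), p=pb) + 1)
        rows = []
        for i in range(n):
            rows.append([tuple(genos_a[j][i]) for j in range(L)])
        for i in range(n):
            rows.append([tuple(genos_b[j][i]) for j in range(L)])
        gm = make_matrix(rows, ["A"] * n + ["B"] * n,
                         ids=[f"i{k}" for k in range(2 * n)])
        theta = weir_cockerham_theta(gm, ["A", "B"])
        assert theta == pytest.approx(0.25, abs=0.03)

    def test_pairwise_matrix_symmetric(self, two_group_toy):
        res = weir_cockerham_theta(two_group_toy, ["A", "B"],
                                   scope="pairwise_matrix")
        assert res.pairwise.shape == (2, 2)
        assert res.pairwise[0, 1] == res.pairwise[1, 0]


class TestAmova:
    def test_perfect_separation_gives_one(self):
        n = 12
        d = np.ones((n, n)) - np.eye(n)
        d[:6, :6] = 0.0
        d[6:, 6:] = 0.0
        np.fill_diagonal(d, 0.0)
        phi, p = amova_phipt(d, ["A"] * 6 + ["B"] * 6, n_perm=199, seed=0)
        assert phi == pytest.approx(1.0)
        assert p < 0.05

    def test_shuffled_labels_near_zero_on_average(self):
        # under label exchange Phi-PT is centred at ~0 and its permutation
        # p-value is unremarkable (the 1-df among-group term is noisy, so a
        # single draw can wander; the p-value is the calibrated check)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 3))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(axis=2))
        phis, ps = [], []
        for seed in range(5):
            labels = rng.permutation(["A"] * 15 + ["B"] * 15).tolist()
            phi, p = amova_phipt(d, labels, n_perm=99, seed=seed)
            phis.append(phi)
            ps.append(p)
        assert abs(np.mean(phis)) < 0.1
        assert max(ps) > 0.1

    def test_haplotype_fixture_wolves_vs_village_dogs(self):
        # WIT (monomorphic W14) vs DIT (8 dog haplotypes) share no haplotype;
        # the exact mismatch-distance Phi-PT, derived by hand from the count
        # table (SS_w = 728/62, SS_t = 4634/188, n0 = 94 - 4930/94), is 0.7067
        counts = haplotype_counts("table3")
        haps, labels = [], []
        for hap, row in counts[["WIT", "DIT"]].iterrows():
            for g in ("WIT", "DIT"):
                haps.extend([hap] * int(row[g]))
                labels.extend([g] * int(row[g]))
        phi, p = amova_phipt(mismatch_distances(haps), labels, n_perm=99, seed=3)
        assert phi == pytest.approx(0.70671, abs=1e-4)
        assert p <= 0.01

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            amova_phipt(np.array([[0.0, 1.0], [2.0, 0.0]]), ["A", "B"])


def test_allele_count_distance_zero_iff_same_genotype():
    gm = make_matrix([[(1, 2)], [(2, 1)], [(1, 1)]], ["A", "A", "B"])
    d = allele_count_distances(gm)
    assert d[0, 1] == 0.0
    assert d[0, 2] > 0.0
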