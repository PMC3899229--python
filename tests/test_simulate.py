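import numpy as np
import pytest

from hybridkit.diversity import diversity_summary
from hybridkit.differentiation import weir_cockerham_theta
from hybridkit.simulate import (HybridClass, SyntheticPopSpec,
                                expected_ancestry, simulate_class_panel,
                                simulate_cross, simulate_parental_pops)

from conftest import make_matrix


class TestSpecValidation:
    def test_infeasible_heterozygosity_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SyntheticPopSpec(alleles_per_locus=2,
                             target_ho={"W": 0.9, "D": 0.5})

    def test_bad_fst_rejected(self):
        with pytest.raises(ValueError):
            SyntheticPopSpec(target_fst=1.5)

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError):
            SyntheticPopSpec(n_individuals={"W": 1, "D": 60})


class TestParentalPops:
    def test_calibration_targets_met(self, parental_pops):
        theta = weir_cockerham_theta(parental_pops, ["W", "D"])
        assert 0.22 <= theta <= 0.28
        for pop, target in (("W", 0.46), ("D", 0.71)):
            s = diversity_summary(parental_pops, pop)
            assert s.ho == pytest.approx(target, abs=0.05)

    def test_deterministic_given_seed(self):
        spec = SyntheticPopSpec(n_loci=10, seed=5,
                                n_individuals={"W": 12, "D": 12})
        a = simulate_parental_pops(spec)
        b = simulate_parental_pops(spec)
        assert a == b

    def test_low_divergence_limit(self):
        # with mild thinning (Ho targets near the ancestral diversity) a
        # near-zero divergence target is attainable
        spec = SyntheticPopSpec(n_loci=30, target_fst=0.02,
                                target_ho={"W": 0.75, "D": 0.75},
                                n_individuals={"W": 40, "D": 40},
                                fst_tolerance=0.02, seed=3)
        gm = simulate_parental_pops(spec)
        assert weir_cockerham_theta(gm, ["W", "D"]) <= 0.05


class TestCross:
    def test_fixed_pools_give_all_heterozygotes(self):
        a = make_matrix([[(1, 1)]] * 4, ["A"] * 4, ids=[f"a{k}" for k in range(4)],
                        locus_alleles=[(1, 2)])
        b = make_matrix([[(2, 2)]] * 4, ["B"] * 4, ids=[f"b{k}" for k in range(4)],
                        locus_alleles=[(1, 2)])
        off = simulate_cross(a, b, 20, seed=0)
        assert ((np.sort(off.calls, axis=2) == [1, 2]).all())

    def test_offspring_frequencies_converge_to_pool(self):
        rng = np.random.default_rng(4)
        pool = make_matrix(
            [[tuple(rng.choice([1, 2, 3], size=2, p=[0.5, 0.3, 0.2]))]
             for _ in range(200)],
            ["P"] * 200, ids=[f"p{k}" for k in range(200)],
            locus_alleles=[(1, 2, 3)])
        off = simulate_cross(pool, pool, 1000, seed=1)
        copies = off.calls[:, 0, :].ravel()
        pool_copies = pool.calls[:, 0, :].ravel()
        from scipy import stats
        pool_freq = np.bincount(pool_copies, minlength=4)[1:] / pool_copies.size
        counts = np.bincount(copies, minlength=4)[1:]
        gof = stats.chisquare(counts, pool_freq * copies.size)
        assert gof.pvalue > 0.001

    def test_reproducible_with_seed(self):
        a = make_matrix([[(1, 2)]] * 4, ["A"] * 4, ids=[f"a{k}" for k in range(4)])
        off1 = simulate_cross(a, a, 10, seed=9)
        off2 = simulate_cross(a, a, 10, seed=9)
        assert off1 == off2


class TestClassPanel:
    @pytest.fixture
    def diagnostic_parents(self):
        w = make_matrix([[(1, 1)] * 6] * 10, ["W"] * 10,
                        ids=[f"w{k}" for k in range(10)],
                        locus_alleles=[(1, 2)] * 6)
        d = make_matrix([[(2, 2)] * 6] * 10, ["D"] * 10,
                        ids=[f"d{k}" for k in range(10)],
                        locus_alleles=[(1, 2)] * 6)
        return w, d

    def test_f1_all_heterozygous_on_diagnostic_loci(self, diagnostic_parents):
        w, d = diagnostic_parents
        sim = simulate_class_panel(w, d, [HybridClass.F1], 30, seed=2)
        calls = np.sort(sim.matrix.calls, axis=2)
        assert (calls == [1, 2]).all()

    def test_bc2w_w_allele_fraction_near_pedigree_expectation(self):
        w = make_matrix([[(1, 1)] * 39] * 20, ["W"] * 20,
                        ids=[f"w{k}" for k in range(20)],
                        locus_alleles=[(1, 2)] * 39)
        d = make_matrix([[(2, 2)] * 39] * 20, ["D"] * 20,
                        ids=[f"d{k}" for k in range(20)],
                        locus_alleles=[(1, 2)] * 39)
        sim = simulate_class_panel(w, d, [HybridClass.BC2W], 60, seed=7)
        w_frac = (sim.matrix.calls == 1).mean()
        # binomial s.e. of the mean W-allele fraction over 60 x 39 x 2 copies
        assert w_frac == pytest.approx(0.875, abs=0.02)

    def test_full_panel_bookkeeping(self, parental_pops):
        w = parental_pops.subset_individuals(parental_pops.group_mask("W"))
        d = parental_pops.subset_individuals(parental_pops.group_mask("D"))
        classes = list(HybridClass)[2:]  # all non-parental classes
        sim = simulate_class_panel(w, d, classes, 60, seed=7)
        assert sim.matrix.n_individuals == 60 * len(classes)
        labels = {ind.group for ind in sim.matrix.individuals}
        assert labels == {c.value for c in classes}
        sim2 = simulate_class_panel(w, d, classes, 60, seed=7)
        assert sim.matrix == sim2.matrix
        sim3 = simulate_class_panel(w, d, classes, 60, seed=8)
        assert sim.matrix != sim3.matrix

    def test_class_w_fractions_match_expected_ancestry(self, parental_pops):
        # on diagnostic-enough synthetic pops, use truly diagnostic loci to
        # check every class's pedigree expectation within 3 binomial s.e.
        w = make_matrix([[(1, 1)] * 39] * 30, ["W"] * 30,
                        ids=[f"w{k}" for k in range(30)],
                        locus_alleles=[(1, 2)] * 39)
        d = make_matrix([[(2, 2)] * 39] * 30, ["D"] * 30,
                        ids=[f"d{k}" for k in range(30)],
                        locus_alleles=[(1, 2)] * 39)
        classes = list(HybridClass)
        sim = simulate_class_panel(w, d, classes, 60, seed=3)
        for cls in classes:
            mask = np.array([ind.group == cls.value
                             for ind in sim.matrix.individuals])
            frac = (sim.matrix.calls[mask] == 1).mean()
            expect = expected_ancestry(cls)
            n_copies = mask.sum() * 39 * 2
            se = np.sqrt(max(expect * (1 - expect), 1e-9) / n_copies)
            # pool-frequency resampling inflates variance beyond the pure
            # binomial s.e.; allow 3 s.e. plus a small floor
            assert abs(frac - expect) < max(3 * se, 0.02) + 0.02


class TestExpectedAncestry:
    @pytest.mark.parametrize("cls,value", [
        (HybridClass.F1, 0.5), (HybridClass.F2, 0.5),
        (HybridClass.BC1W, 0.75), (HybridClass.BC2W, 0.875),
        (HybridClass.BC3W, 0.9375), (HybridClass.BC1D, 0.25),
        (HybridClass.BC3D, 0.0625), (HybridClass.P_W, 1.0),
    ])
    def test_pedigree_expectations(self, cls, value):
        assert expected_ancestry(cls) == value
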