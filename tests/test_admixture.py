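import numpy as np
import pandas as pd
import pytest

from hybridkit.admixture import (AdmixtureConfig, credible_intervals, delta_k,
                                 estimate_lnpd, run_admixture_mcmc)
from hybridkit.simulate import HybridClass, simulate_class_panel

from conftest import make_matrix


def _diagnostic_panel(n_per=15, L=20):
    """Two fixed-difference populations plus one fully heterozygous test
    individual."""
    rows = [[(1, 1)] * L for _ in range(n_per)]
    rows += [[(2, 2)] * L for _ in range(n_per)]
    rows += [[(1, 2)] * L]
    groups = ["W"] * n_per + ["D"] * n_per + ["X"]
    return make_matrix(rows, groups, ids=[f"i{k}" for k in range(2 * n_per + 1)])


SMALL = dict(n_burnin=200, n_iter=600, n_chains=2, thin=5)


class TestSampler:
    def test_k1_gives_unit_ancestry(self, two_group_toy):
        res = run_admixture_mcmc(two_group_toy, AdmixtureConfig(K=1, **SMALL))
        assert (res.q.to_numpy() == 1.0).all()

    def test_q_rows_and_cluster_freqs_normalised(self, two_group_toy):
        res = run_admixture_mcmc(two_group_toy, AdmixtureConfig(K=2, seed=1, **SMALL))
        assert np.allclose(res.q.sum(axis=1), 1.0)
        sums = res.cluster_freqs.sum(axis=2)
        assert np.allclose(sums, 1.0)

    def test_heterozygous_individual_splits_evenly(self):
        gm = _diagnostic_panel()
        res = run_admixture_mcmc(gm, AdmixtureConfig(K=2, seed=3, **SMALL))
        q = res.q.loc["i30"]
        assert q.max() == pytest.approx(0.5, abs=0.05)

    def test_separated_populations_recovered(self, parental_pops):
        cfg = AdmixtureConfig(K=2, n_burnin=300, n_iter=900, n_chains=1,
                              seed=4, thin=5)
        res = run_admixture_mcmc(parental_pops, cfg)
        groups = pd.Series([i.group for i in parental_pops.individuals],
                           index=res.q.index)
        own = res.q.groupby(groups).mean().max(axis=1)
        assert (own >= 0.95).all()

    def test_deterministic_given_seed(self, two_group_toy):
        cfg = AdmixtureConfig(K=2, seed=11, **SMALL)
        a = run_admixture_mcmc(two_group_toy, cfg)
        b = run_admixture_mcmc(two_group_toy, cfg)
        assert a.q.equals(b.q)
        assert a.lnpd == b.lnpd

    def test_ci_brackets_posterior_mean(self, two_group_toy):
        res = run_admixture_mcmc(two_group_toy, AdmixtureConfig(K=2, seed=2, **SMALL))
        assert (res.ci_lower.to_numpy() <= res.q.to_numpy() + 1e-12).all()
        assert (res.ci_upper.to_numpy() >= res.q.to_numpy() - 1e-12).all()

    def test_popinfo_pins_reference_individuals(self):
        gm = _diagnostic_panel()
        for ind in gm.individuals:
            ind.popflag = ind.group in ("W", "D")
        cfg = AdmixtureConfig(K=2, use_popinfo=True,
                              update_freqs_from_flagged_only=True, seed=5, **SMALL)
        res = run_admixture_mcmc(gm, cfg)
        assert res.cluster_labels[:2] == ["W", "D"]
        assert res.q.loc["i0", "W"] == 1.0
        assert res.q.loc["i30", "W"] == pytest.approx(0.5, abs=0.05)

    def test_popinfo_without_flags_errors(self, two_group_toy):
        cfg = AdmixtureConfig(K=2, use_popinfo=True, **SMALL)
        with pytest.raises(ValueError, match="flagged"):
            run_admixture_mcmc(two_group_toy, cfg)

    def test_known_ancestry_recovered(self, parental_pops):
        # admixed individuals with known q*: each copy drawn from W with
        # probability q*; posterior means should track q* closely
        rng = np.random.default_rng(6)
        from hybridkit.core import allele_frequencies

        ft = allele_frequencies(parental_pops)
        q_true = np.linspace(0.05, 0.95, 24)
        rows = []
        for q in q_true:
            row = []
            for loc in parental_pops.loci:
                copies = []
                for _ in range(2):
                    src = "W" if rng.random() < q else "D"
                    vec = ft.freqs[src][loc.name]
                    labels = list(vec)
                    copies.append(int(rng.choice(labels, p=np.array(list(vec.values())))))
                row.append(tuple(copies))
            rows.append(row)
        from hybridkit.core import GenotypeMatrix, IndividualMeta

        calls = np.array([[list(pair) for pair in row] for row in rows])
        admixed = GenotypeMatrix(
            [IndividualMeta(id=f"x{k}", group="X") for k in range(len(q_true))],
            list(parental_pops.loci), calls)
        panel = parental_pops.concat(admixed)
        cfg = AdmixtureConfig(K=2, n_burnin=400, n_iter=1200, n_chains=1,
                              seed=7, thin=5)
        res = run_admixture_mcmc(panel, cfg)
        groups = pd.Series([i.group for i in panel.individuals], index=res.q.index)
        wcol = res.q.loc[groups == "W"].mean().idxmax()
        est = res.q.loc[groups == "X", wcol].to_numpy()
        r = np.corrcoef(q_true, est)[0, 1]
        assert r > 0.95


class TestEvidence:
    def test_lnpd_zero_variance(self):
        assert estimate_lnpd(np.full(200, -100.0)) == -100.0

    def test_lnpd_arithmetic(self):
        trace = np.array([-100.0, -102.0] * 100)
        assert estimate_lnpd(trace) == pytest.approx(-101.0 - 1.0 / 2.0)

    def test_lnpd_rejects_nonfinite(self):
        trace = np.full(200, -5.0)
        trace[3] = np.nan
        with pytest.raises(ValueError):
            estimate_lnpd(trace)

    def test_delta_k_arithmetic(self):
        lnpd = {1: [-5000.0, -5000.1], 2: [-4000.0, -4000.1],
                3: [-3900.0, -3900.1], 4: [-3890.0, -3890.1]}
        ks = delta_k(lnpd)
        sd = np.std([-4000.0, -4000.1], ddof=1)
        assert ks.delta_k[2] == pytest.approx(abs(-3900 - 2 * -4000 + -5000) / sd)
        assert ks.best_k == 2

    def test_linear_sequence_gives_zero(self):
        lnpd = {k: [-1000.0 * (5 - k) + d for d in (0.0, 0.3)] for k in (1, 2, 3, 4)}
        ks = delta_k(lnpd)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in ks.delta_k.values())

    def test_nonconsecutive_k_rejected(self):
        with pytest.raises(ValueError):
            delta_k({1: [0, 0], 3: [0, 0]})

    def test_two_population_data_select_k2(self, parental_pops):
        sub = parental_pops.subset_loci(parental_pops.locus_names[:15])
        keep = np.zeros(sub.n_individuals, dtype=bool)
        keep[:20] = True
        keep[60:80] = True
        sub = sub.subset_individuals(keep)
        lnpd = {}
        for k in (1, 2, 3):
            cfg = AdmixtureConfig(K=k, n_burnin=200, n_iter=600, n_chains=2,
                                  seed=8, thin=10)
            lnpd[k] = run_admixture_mcmc(sub, cfg).lnpd
        assert delta_k(lnpd).best_k == 2


class TestCredibleIntervals:
    def test_constant_trace_gives_zero_width(self):
        samples = np.full((50, 3, 2), 0.5)
        lo, hi = credible_intervals(samples)
        assert np.allclose(lo, hi)

    def test_panel_reduction_widens_parental_intervals(self, parental_pops):
        widths = {}
        for n_loci in (39, 12):
            sub = parental_pops.subset_loci(parental_pops.locus_names[:n_loci])
            cfg = AdmixtureConfig(K=2, n_burnin=300, n_iter=900, n_chains=1,
                                  seed=9, thin=5)
            res = run_admixture_mcmc(sub, cfg)
            w = (res.ci_upper - res.ci_lower).to_numpy().mean()
            widths[n_loci] = w
        assert widths[12] > widths[39]
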