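"""Likelihood-based assignment and hybrid-class inference.

Four complementary approaches:

* :func:`rannala_mountain_score` — leave-one-out Bayesian assignment of an
  individual to candidate groups via the posterior-predictive genotype
  probability under a Dirichlet(1/k) prior on each group's allele counts.
* :func:`newhybrids_posterior` — MCMC posterior over six genotype classes
  (two parentals, F1, F2, and the two first backcrosses), where each class
  fixes the probabilities that a locus's two gene copies originate from
  (W,W), (W,D) or (D,D).
* :func:`flock_partition` — non-Bayesian iterated reallocation clustering
  with a plateau (run-agreement) report.
* :func:`admixture_null_test` — empirical-null calibration of admixture
  coefficients from simulated non-admixed genotypes, flagging observed
  individuals whose non-self ancestry exceeds the (1-alpha) null quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .admixture import AdmixtureConfig, run_admixture_mcmc
from .core import (MISSING, GenotypeMatrix, IndividualMeta, Locus,
                   allele_frequencies)

# class order is fixed: parental wolf, parental dog, F1, F2, backcross to
# wolf, backcross to dog
NH_CLASSES = ["P_W", "P_D", "F1", "F2", "BC_W", "BC_D"]

# phi_c: P(copies originate from (W,W), (W,D), (D,D)) per class
NH_ORIGIN_WEIGHTS = np.array([
    [1.00, 0.00, 0.00],   # P_W
    [0.00, 0.00, 1.00],   # P_D
    [0.00, 1.00, 0.00],   # F1
    [0.25, 0.50, 0.25],   # F2
    [0.50, 0.50, 0.00],   # BC_W
    [0.00, 0.50, 0.50],   # BC_D
])


# -- Rannala-Mountain assignment -------------------------------------------------


@dataclass
class AssignmentScore:
    individual: str
    log_likelihood: dict[str, float]
    percent: dict[str, float]
    exclusion_p: dict[str, float] | None = None

    @property
    def best_group(self) -> str:
        return max(self.log_likelihood, key=self.log_likelihood.get)


def _group_counts(gm: GenotypeMatrix, group: str) -> list[dict[int, int]]:
    mask = gm.group_mask(group)
    out = []
    for j in range(gm.n_loci):
        copies = gm.calls[mask, j, :].ravel()
        copies = copies[copies != MISSING]
        labels, counts = np.unique(copies, return_counts=True)
        out.append({int(a): int(c) for a, c in zip(labels, counts)})
    return out


def rannala_mountain_score(gm: GenotypeMatrix, individual: str,
                           candidate_groups: list[str],
                           leave_one_out: bool = True) -> AssignmentScore:
    """Assignment score of one individual against candidate groups.

    Per locus the genotype probability is posterior-predictive under a
    Dirichlet(1/k_l) prior on the group's allele counts (k_l = number of
    alleles at the locus), with the individual's own gene copies removed
    when it belongs to the group and ``leave_one_out`` is set. Missing loci
    are skipped; percent scores are the normalised likelihoods x 100.
    """
    idx = {ind.id: i for i, ind in enumerate(gm.individuals)}
    i = idx[individual]
    own_group = gm.individuals[i].group
    logs: dict[str, float] = {}
    for g in candidate_groups:
        counts = _group_counts(gm, g)
        total = 0.0
        for j, locus in enumerate(gm.loci):
            a, b = gm.calls[i, j]
            if a == MISSING or b == MISSING:
                continue
            cnt = dict(counts[j])
            if leave_one_out and g == own_group:
                cnt[int(a)] = cnt.get(int(a), 0) - 1
                cnt[int(b)] = cnt.get(int(b), 0) - 1
            k = max(len(locus.alleles), 1)
            n = sum(cnt.values())
            prior = 1.0 / k
            p1 = (cnt.get(int(a), 0) + prior) / (n + 1.0)
            p2 = (cnt.get(int(b), 0) + prior + (1.0 if a == b else 0.0)) / (n + 2.0)
            prob = p1 * p2 * (1.0 if a == b else 2.0)
            total += float(np.log(prob))
        logs[g] = total
    arr = np.array([logs[g] for g in candidate_groups])
    rel = np.exp(arr - arr.max())
    pct = 100.0 * rel / rel.sum()
    return AssignmentScore(individual, logs,
                           {g: float(v) for g, v in zip(candidate_groups, pct)})


def monte_carlo_exclusion(gm: GenotypeMatrix, individual: str,
                          candidate_groups: list[str], n_sim: int = 1000,
                          seed: int = 0) -> dict[str, float]:
    """Monte-Carlo exclusion p-value per candidate group.

    Simulates ``n_sim`` genotypes from each group's allele frequencies and
    reports the fraction whose assignment log-likelihood is at most the
    individual's — a small p excludes the group as a plausible origin. Off
    the main path (percent scores are the primary output); provided for
    exclusion-style reporting.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    idx = {ind.id: i for i, ind in enumerate(gm.individuals)}
    focal = gm.calls[[idx[individual]]]
    for g in candidate_groups:
        counts = _group_counts(gm, g)
        base = float(_genotype_loglik(counts, gm.loci, focal)[0])
        sims = simulate_parental_genotypes(gm, g, n_sim,
                                           int(rng.integers(0, 2 ** 31 - 1)),
                                           id_prefix=f"mc{g}")
        sim_ll = _genotype_loglik(counts, gm.loci, sims.calls)
        worse = int((sim_ll <= base).sum())
        out[g] = (worse + 1) / (n_sim + 1)
    return out


def self_assignment_accuracy(gm: GenotypeMatrix, groups: list[str],
                             loci: list[str] | None = None) -> float:
    """Leave-one-out fraction of individuals assigned back to their own group."""
    sub = gm.subset_loci(loci) if loci is not None else gm
    members = [ind for ind in sub.individuals if ind.group in groups]
    hits = 0
    for ind in members:
        score = rannala_mountain_score(sub, ind.id, groups, leave_one_out=True)
        hits += score.best_group == ind.group
    return hits / len(members)


# -- NewHybrids-style class posterior --------------------------------------------


@dataclass
class NewHybridsConfig:
    n_iter: int = 20_000
    n_burnin: int = 2_000
    prior_mode: str = "uniform"   # or "jeffreys_like"
    jeffreys_constant: float = 0.5
    n_chains: int = 2
    seed: int = 0

    @property
    def freq_prior(self) -> float:
        if self.prior_mode == "uniform":
            return 1.0
        if self.prior_mode == "jeffreys_like":
            return self.jeffreys_constant
        raise ValueError(f"unknown prior_mode {self.prior_mode!r}")


@dataclass
class ClassPosterior:
    posterior: pd.DataFrame       # individuals x six classes
    map_class: pd.Series
    prior_mode: str
    gelman_rubin: float | None = None

    def __post_init__(self) -> None:
        sums = self.posterior.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("class posterior rows must sum to 1")


def _nh_genotype_likelihoods(tw: np.ndarray, td: np.ndarray, g: np.ndarray,
                             larr: np.ndarray, obs: np.ndarray
                             ) -> np.ndarray:
    """(N, L, 3) genotype probabilities under origins (W,W), (W,D), (D,D)."""
    a1, a2 = g[:, :, 0], g[:, :, 1]
    het = (a1 != a2) & obs
    w1, w2 = tw[larr, a1], tw[larr, a2]
    d1, d2 = td[larr, a1], td[larr, a2]
    p_ww = w1 * w2 * np.where(het, 2.0, 1.0)
    p_dd = d1 * d2 * np.where(het, 2.0, 1.0)
    p_wd = w1 * d2 + np.where(het, w2 * d1, 0.0)
    return np.stack([p_ww, p_wd, p_dd], axis=2)


def newhybrids_posterior(gm: GenotypeMatrix, reference_w: str | None,
                         reference_d: str | None,
                         cfg: NewHybridsConfig | None = None) -> ClassPosterior:
    """Posterior probability that each genotype belongs to each of six
    classes {P_W, P_D, F1, F2, BC_W, BC_D}.

    Gibbs sampling over per-individual class labels, class mixing
    proportions (Dirichlet(1) prior) and the two source allele-frequency
    vectors (Dirichlet prior: 1 per allele for ``uniform``, 0.5 for
    ``jeffreys_like``). Individuals in the named reference groups have their
    class fixed to the corresponding parental. Loci monomorphic across the
    dataset are dropped.
    """
    cfg = cfg or NewHybridsConfig()
    poly = [loc.name for loc in gm.loci if len(loc.alleles) > 1]
    if len(poly) < gm.n_loci:
        gm = gm.subset_loci(poly)
    if gm.n_loci == 0:
        raise ValueError("no polymorphic loci shared by the dataset")

    amax = max(len(loc.alleles) for loc in gm.loci)
    N, L = gm.n_individuals, gm.n_loci
    G = np.zeros((N, L, 2), dtype=np.int64)
    valid = np.zeros((L, amax), dtype=bool)
    for j, locus in enumerate(gm.loci):
        valid[j, : len(locus.alleles)] = True
        index = {a: k for k, a in enumerate(locus.alleles)}
        for a, k in index.items():
            G[:, j, :][gm.calls[:, j, :] == a] = k
    obs = (gm.calls != MISSING).all(axis=2)   # per-genotype completeness
    larr = np.arange(L)[None, :]

    fixed = np.full(N, -1, dtype=np.int64)
    for i, ind in enumerate(gm.individuals):
        if reference_w is not None and ind.group == reference_w:
            fixed[i] = 0
        elif reference_d is not None and ind.group == reference_d:
            fixed[i] = 1
    free = fixed < 0
    prior = cfg.freq_prior

    master = np.random.default_rng(cfg.seed)
    chain_seeds = master.integers(0, 2 ** 31 - 1, size=cfg.n_chains)
    post_chains, lnl_chains = [], []
    for s in chain_seeds:
        rng = np.random.default_rng(int(s))
        tw = rng.gamma(prior, size=(L, amax)) * valid
        tw /= tw.sum(axis=1, keepdims=True)
        td = rng.gamma(prior, size=(L, amax)) * valid
        td /= td.sum(axis=1, keepdims=True)
        pi = np.full(6, 1.0 / 6.0)
        post = np.zeros((N, 6))
        lnl_trace = np.empty(cfg.n_iter)
        total = cfg.n_burnin + cfg.n_iter
        for sweep in range(total):
            p_org = _nh_genotype_likelihoods(tw, td, G, larr, obs)  # (N,L,3)
            p_cls = np.einsum("nlo,co->nlc", p_org, NH_ORIGIN_WEIGHTS)
            logp = np.where(obs[:, :, None], np.log(np.maximum(p_cls, 1e-300)), 0.0)
            loglik_c = logp.sum(axis=1) + np.log(pi)[None, :]      # (N,6)
            w = np.exp(loglik_c - loglik_c.max(axis=1, keepdims=True))
            w /= w.sum(axis=1, keepdims=True)
            u = rng.random((N, 1))
            z = (w.cumsum(axis=1) < u).sum(axis=1)
            z = np.where(free, z, fixed)

            # per-locus copy origins given the class
            phi_z = NH_ORIGIN_WEIGHTS[z][:, None, :]               # (N,1,3)
            wo = phi_z * p_org
            wo_sum = np.maximum(wo.sum(axis=2, keepdims=True), 1e-300)
            uo = rng.random((N, L, 1)) * wo_sum
            org = (wo.cumsum(axis=2) < uo).sum(axis=2)             # 0 WW,1 WD,2 DD

            # for heterospecific (W,D) copies of heterozygotes: which allele
            # came from the wolf side
            a1, a2 = G[:, :, 0], G[:, :, 1]
            het = (a1 != a2) & obs
            w1d2 = tw[larr, a1] * td[larr, a2]
            w2d1 = tw[larr, a2] * td[larr, a1]
            pick = rng.random((N, L)) * np.maximum(w1d2 + w2d1, 1e-300) < w1d2
            # allele index contributed to each source pool (W then D)
            to_w = np.where(pick | ~het, a1, a2)
            to_d = np.where(pick | ~het, a2, a1)

            mask_obs = obs
            cw = np.zeros((L, amax))
            cd = np.zeros((L, amax))
            sel_ww = (org == 0) & mask_obs
            sel_wd = (org == 1) & mask_obs
            sel_dd = (org == 2) & mask_obs
            lflat = np.broadcast_to(np.arange(L)[None, :], (N, L))
            np.add.at(cw, (lflat[sel_ww], a1[sel_ww]), 1.0)
            np.add.at(cw, (lflat[sel_ww], a2[sel_ww]), 1.0)
            np.add.at(cd, (lflat[sel_dd], a1[sel_dd]), 1.0)
            np.add.at(cd, (lflat[sel_dd], a2[sel_dd]), 1.0)
            np.add.at(cw, (lflat[sel_wd], to_w[sel_wd]), 1.0)
            np.add.at(cd, (lflat[sel_wd], to_d[sel_wd]), 1.0)

            tw = rng.gamma(prior + cw) * valid
            tw /= np.maximum(tw.sum(axis=1, keepdims=True), 1e-300)
            td = rng.gamma(prior + cd) * valid
            td /= np.maximum(td.sum(axis=1, keepdims=True), 1e-300)

            counts = np.bincount(z, minlength=6).astype(float)
            pi = rng.dirichlet(1.0 + counts)

            if sweep >= cfg.n_burnin:
                post[np.arange(N), z] += 1.0
                lnl_trace[sweep - cfg.n_burnin] = float(
                    logp.sum(axis=1)[np.arange(N), z].sum())
        post_chains.append(post / cfg.n_iter)
        lnl_chains.append(lnl_trace)

    gr = _gelman_rubin(lnl_chains) if cfg.n_chains >= 2 else None
    if gr is not None and gr > 1.2:
        warnings.warn(f"chains may not have converged (Gelman-Rubin {gr:.2f})")
    post = np.mean(post_chains, axis=0)
    post /= post.sum(axis=1, keepdims=True)
    ids = [ind.id for ind in gm.individuals]
    df = pd.DataFrame(post, index=ids, columns=NH_CLASSES)
    return ClassPosterior(df, df.idxmax(axis=1), cfg.prior_mode, gr)


def _gelman_rubin(traces: list[np.ndarray]) -> float:
    m = len(traces)
    n = min(len(t) for t in traces)
    x = np.stack([t[:n] for t in traces])
    means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


# -- Flock-style iterated reallocation -------------------------------------------


@dataclass
class FlockResult:
    assignment: np.ndarray        # modal partition, coded 0..k-1
    agreement: float              # fraction of runs matching the modal partition
    plateau: int                  # length of the modal run streak
    runs: list[np.ndarray] = field(repr=False, default_factory=list)


def _genotype_loglik(counts: list[dict[int, int]], loci: list[Locus],
                     calls: np.ndarray) -> np.ndarray:
    """Log-likelihood of each individual's genotype under a group's
    posterior-mean allele frequencies (Dirichlet 1/k smoothing)."""
    n_ind = calls.shape[0]
    out = np.zeros(n_ind)
    for j, locus in enumerate(loci):
        k = max(len(locus.alleles), 1)
        cnt = counts[j]
        n = sum(cnt.values())
        denom = n + 1.0
        a, b = calls[:, j, 0], calls[:, j, 1]
        pa = np.array([(cnt.get(int(x), 0) + 1.0 / k) / denom if x != MISSING else 1.0
                       for x in a])
        pb = np.array([(cnt.get(int(x), 0) + 1.0 / k) / denom if x != MISSING else 1.0
                       for x in b])
        het = (a != b) & (a != MISSING) & (b != MISSING)
        out += np.log(pa) + np.log(pb) + np.where(het, np.log(2.0), 0.0)
    return out


def flock_partition(gm: GenotypeMatrix, k: int, n_runs: int = 50,
                    n_reallocations: int = 20, lod_threshold: float = 0.0,
                    seed: int = 0) -> FlockResult:
    """Iterated-reallocation partitioning into ``k`` groups.

    Each run starts from a random partition and repeats ``n_reallocations``
    times: estimate group allele frequencies, then move every individual to
    the group maximising its genotype log-likelihood provided the log10
    likelihood ratio over the best alternative reaches ``lod_threshold``.
    An emptied group is reseeded with the currently worst-fitting individual.
    The plateau report counts how many runs reproduce the modal partition
    (up to label permutation).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    N = gm.n_individuals
    runs: list[np.ndarray] = []
    for _ in range(n_runs):
        part = rng.integers(0, k, size=N)
        fit = np.zeros(N)
        for _ in range(n_reallocations):
            for g in range(k):
                if not (part == g).any():
                    # reseed an emptied group with the worst-fitting individual
                    part[int(np.argmin(fit))] = g
            logliks = np.empty((N, k))
            for g in range(k):
                counts = _counts_from_mask(gm, part == g)
                logliks[:, g] = _genotype_loglik(counts, gm.loci, gm.calls)
            order = np.argsort(logliks, axis=1)
            best, second = order[:, -1], order[:, -2]
            lod = (logliks[np.arange(N), best] - logliks[np.arange(N), second]) / np.log(10.0)
            part = np.where(lod >= lod_threshold, best, part)
            fit = logliks[np.arange(N), part]
        runs.append(_canonical_partition(part))
    keys = ["|".join(map(str, r)) for r in runs]
    vals, counts = np.unique(keys, return_counts=True)
    modal_key = vals[np.argmax(counts)]
    agreement = counts.max() / n_runs
    # longest consecutive streak of the modal partition
    streak = best_streak = 0
    for key in keys:
        streak = streak + 1 if key == modal_key else 0
        best_streak = max(best_streak, streak)
    modal = runs[keys.index(modal_key)]
    return FlockResult(modal, float(agreement), int(best_streak), runs)


def _counts_from_mask(gm: GenotypeMatrix, mask: np.ndarray) -> list[dict[int, int]]:
    out = []
    for j in range(gm.n_loci):
        copies = gm.calls[mask, j, :].ravel()
        copies = copies[copies != MISSING]
        labels, counts = np.unique(copies, return_counts=True)
        out.append({int(a): int(c) for a, c in zip(labels, counts)})
    return out


def _canonical_partition(part: np.ndarray) -> np.ndarray:
    """Relabel clusters by first appearance so partitions compare up to
    label permutation."""
    mapping: dict[int, int] = {}
    out = np.empty_like(part)
    for i, g in enumerate(part):
        if g not in mapping:
            mapping[g] = len(mapping)
        out[i] = mapping[g]
    return out


# -- empirical-null admixture significance ---------------------------------------


@dataclass
class NullCalibration:
    null_values: dict[str, np.ndarray]   # per reference group
    thresholds: dict[str, float]
    alpha: float
    significant: pd.DataFrame            # observed individuals: stats + call


def simulate_parental_genotypes(gm: GenotypeMatrix, group: str, n: int,
                                seed: int, id_prefix: str | None = None
                                ) -> GenotypeMatrix:
    """Draw non-admixed genotypes from a group's estimated allele
    frequencies under Hardy-Weinberg (used to build the admixture null)."""
    freqs = allele_frequencies(gm, [group])
    rng = np.random.default_rng(seed)
    calls = np.empty((n, gm.n_loci, 2), dtype=np.int64)
    for j, locus in enumerate(gm.loci):
        vec = freqs.freqs[group][locus.name]
        if not vec:
            raise ValueError(f"no frequency data for {group} x {locus.name}")
        labels = np.array(list(vec))
        p = np.array(list(vec.values()))
        p = p / p.sum()
        calls[:, j, :] = labels[rng.choice(len(labels), size=(n, 2), p=p)]
    prefix = id_prefix or f"sim{group}"
    individuals = [IndividualMeta(id=f"{prefix}_{i+1:04d}", group=f"sim_{group}")
                   for i in range(n)]
    return GenotypeMatrix(individuals, list(gm.loci), calls)


def admixture_null_test(gm: GenotypeMatrix, reference_groups: list[str],
                        n_sim: int = 100, alpha: float = 0.05, seed: int = 0,
                        mcmc: AdmixtureConfig | None = None) -> NullCalibration:
    """Flag significantly admixed individuals against an empirical null.

    ``n_sim`` non-admixed genotypes per reference group are simulated from
    that group's allele frequencies; all of them, the (flagged) reference
    individuals and the remaining observed individuals enter one
    reference-anchored admixture run (K = number of reference groups). The
    null for each group is the distribution of non-self ancestry among its
    simulated parentals; an observed individual is significantly admixed iff
    its non-self ancestry exceeds the (1 - alpha) order-statistic threshold
    of its nearest group's null.
    """
    if n_sim < 20:
        warnings.warn("n_sim < 20 gives a very coarse p-value resolution")
    K = len(reference_groups)
    refs = gm.subset_individuals(
        np.array([ind.group in reference_groups for ind in gm.individuals]))
    for ind in refs.individuals:
        ind.popflag = True
    others = gm.subset_individuals(
        np.array([ind.group not in reference_groups for ind in gm.individuals]))
    combined = refs
    rng = np.random.default_rng(seed)
    for g in reference_groups:
        sims = simulate_parental_genotypes(gm, g, n_sim,
                                           int(rng.integers(0, 2 ** 31 - 1)))
        combined = combined.concat(sims)
    if others.n_individuals:
        combined = combined.concat(others)

    cfg = mcmc or AdmixtureConfig(K=K, n_burnin=500, n_iter=2_000, n_chains=1,
                                  thin=5)
    cfg = AdmixtureConfig(**{**cfg.__dict__, "K": K, "use_popinfo": True,
                             "update_freqs_from_flagged_only": True,
                             "seed": int(rng.integers(0, 2 ** 31 - 1))})
    result = run_admixture_mcmc(combined, cfg)

    nulls: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    for g in reference_groups:
        mask = [ind.group == f"sim_{g}" for ind in combined.individuals]
        qs = result.q.loc[mask]
        non_self = 1.0 - qs[g].to_numpy()
        order = np.sort(non_self)
        rank = int(np.ceil((1.0 - alpha) * n_sim)) - 1
        nulls[g] = non_self
        thresholds[g] = float(order[rank])

    rows = []
    for ind in combined.individuals:
        if ind.popflag or ind.group.startswith("sim_"):
            continue
        q = result.q.loc[ind.id, reference_groups]
        home = q.idxmax()
        non_self = 1.0 - float(q[home])
        rows.append({
            "individual": ind.id, "group": ind.group, "home": home,
            "non_self_ancestry": non_self,
            "threshold": thresholds[home],
            "significant": non_self > thresholds[home],
        })
    sig = pd.DataFrame(rows).set_index("individual") if rows else pd.DataFrame()
    return NullCalibration(nulls, thresholds, alpha, sig)
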