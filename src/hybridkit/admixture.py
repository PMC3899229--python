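"""Bayesian admixture inference for multilocus genotypes.

A Gibbs sampler over the classic admixture model: each allele copy of
individual *i* originates from one of *K* clusters with probability
``q_i`` (Dirichlet(alpha) prior, alpha itself updated by a Metropolis step),
cluster allele frequencies are independent across clusters with a
Dirichlet(lambda) prior, and genotypes are Hardy-Weinberg draws within the
cluster of origin. Optionally, reference individuals can be pinned to
declared clusters (``use_popinfo``), with cluster frequencies learned from
the flagged individuals only.

Model evidence per K is summarised by the usual harmonic-style estimator
``mean(lnL) - var(lnL)/2`` over post-burn-in sweeps, and the number of
clusters can be screened with the second-order rate-of-change statistic
Delta K across consecutive K values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import GenotypeMatrix


@dataclass
class AdmixtureConfig:
    K: int = 2
    n_burnin: int = 4_000
    n_iter: int = 40_000          # post-burn-in sweeps
    alpha_init: float = 1.0
    alpha_max: float = 10.0       # uniform prior on (0, alpha_max]
    alpha_prop_sd: float = 0.025
    lambda_: float = 1.0          # allele-frequency Dirichlet prior
    freq_model: str = "independent"
    use_popinfo: bool = False
    update_freqs_from_flagged_only: bool = False
    n_chains: int = 2
    seed: int = 0
    thin: int = 10                # stored-Q thinning

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_burnin < 0 or self.n_iter <= 0:
            raise ValueError("need n_iter > 0 and n_burnin >= 0")
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")
        if self.freq_model != "independent":
            raise ValueError("only the independent-frequencies model is implemented")


@dataclass
class AdmixtureResult:
    q: pd.DataFrame               # individuals x clusters posterior means
    ci_lower: pd.DataFrame        # 90% credible interval bounds
    ci_upper: pd.DataFrame
    lnpd: list[float]             # per chain
    cluster_freqs: np.ndarray     # K x L x Amax posterior-mean frequencies
    cluster_labels: list[str]
    config: AdmixtureConfig
    lnl_traces: list[np.ndarray] = field(repr=False, default_factory=list)
    q_samples: np.ndarray | None = field(repr=False, default=None)
    alpha_mean: list[float] = field(default_factory=list)  # per chain


def _encode(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Allele-index array (N, L, 2; -1 missing) and validity mask (L, Amax)."""
    amax = max(len(loc.alleles) for loc in gm.loci)
    G = np.full(gm.calls.shape, -1, dtype=np.int64)
    valid = np.zeros((gm.n_loci, amax), dtype=bool)
    for j, locus in enumerate(gm.loci):
        valid[j, : len(locus.alleles)] = True
        index = {a: k for k, a in enumerate(locus.alleles)}
        col = gm.calls[:, j, :]
        for a, k in index.items():
            G[:, j, :][col == a] = k
    return G, valid


def _popinfo_assignments(gm: GenotypeMatrix, K: int) -> tuple[np.ndarray, list[str]]:
    """Flagged-individual cluster indices (-1 for unflagged) and the cluster
    labels derived from flagged groups in first-appearance order."""
    labels: list[str] = []
    assign = np.full(gm.n_individuals, -1, dtype=np.int64)
    for i, ind in enumerate(gm.individuals):
        if not ind.popflag:
            continue
        if ind.group not in labels:
            labels.append(ind.group)
        assign[i] = labels.index(ind.group)
    if not labels:
        raise ValueError("use_popinfo requires at least one flagged individual")
    if len(labels) > K:
        raise ValueError(f"{len(labels)} flagged reference groups exceed K={K}")
    return assign, labels


def _run_chain(G: np.ndarray, valid: np.ndarray, cfg: AdmixtureConfig,
               fixed: np.ndarray, rng: np.random.Generator
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One MCMC chain. Returns (Q posterior mean, stored Q samples,
    lnL trace, P posterior mean)."""
    N, L, _ = G.shape
    K, amax = cfg.K, valid.shape[1]
    obs = G >= 0
    Gs = np.where(obs, G, 0)
    larr = np.arange(L)[None, :, None]
    flagged = fixed >= 0

    # initial state
    P = rng.gamma(cfg.lambda_, size=(K, L, amax)) * valid[None]
    P /= np.maximum(P.sum(axis=2, keepdims=True), 1e-300)
    alpha = cfg.alpha_init
    Q = rng.dirichlet(np.full(K, alpha), size=N)
    Q[flagged] = np.eye(K)[fixed[flagged]]

    include = flagged if (cfg.use_popinfo and cfg.update_freqs_from_flagged_only) else np.ones(N, dtype=bool)
    include_copies = np.broadcast_to(include[:, None, None], G.shape) & obs

    n_store = max(1, cfg.n_iter // cfg.thin)
    q_samples = np.empty((n_store, N, K))
    lnl = np.empty(cfg.n_iter)
    q_mean = np.zeros((N, K))
    p_mean = np.zeros((K, L, amax))
    alpha_sum = 0.0
    stored = 0

    total = cfg.n_burnin + cfg.n_iter
    eyeK = np.eye(K)
    for sweep in range(total):
        # origin of each allele copy
        PG = P.transpose(1, 2, 0)[larr, Gs]          # (N, L, 2, K)
        w = PG * Q[:, None, None, :]
        tot = w.sum(axis=3, keepdims=True)
        tot_safe = np.maximum(tot, 1e-300)
        if K > 1:
            u = rng.random((N, L, 2, 1)) * tot_safe
            z = (w.cumsum(axis=3) < u).sum(axis=3)
        else:
            z = np.zeros((N, L, 2), dtype=np.int64)

        # ancestry update (unflagged only)
        nk = (eyeK[z] * obs[..., None]).sum(axis=(1, 2))  # (N, K)
        gam = rng.gamma(alpha + nk)
        Qn = gam / gam.sum(axis=1, keepdims=True)
        Q = np.where(flagged[:, None], Q, Qn)

        # cluster allele-frequency update
        flat = (z * L + np.arange(L)[None, :, None]) * amax + Gs
        m = np.bincount(flat[include_copies].ravel(),
                        minlength=K * L * amax).reshape(K, L, amax)
        P = rng.gamma(cfg.lambda_ + m) * valid[None]
        P /= np.maximum(P.sum(axis=2, keepdims=True), 1e-300)

        # Metropolis step on the Dirichlet concentration alpha
        if K > 1 and (~flagged).any():
            prop = alpha + rng.normal(0.0, cfg.alpha_prop_sd)
            if 0.0 < prop <= cfg.alpha_max:
                logq = np.log(np.maximum(Q[~flagged], 1e-300)).sum()
                n_free = int((~flagged).sum())

                def _lp(a: float) -> float:
                    return n_free * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * logq
                if np.log(rng.random()) < _lp(prop) - _lp(alpha):
                    alpha = prop

        if sweep >= cfg.n_burnin:
            it = sweep - cfg.n_burnin
            lnl[it] = float(np.log(tot_safe[obs[..., None]]).sum())
            q_mean += Q
            p_mean += P
            alpha_sum += alpha
            if it % cfg.thin == 0 and stored < n_store:
                q_samples[stored] = Q
                stored += 1
    q_mean /= cfg.n_iter
    p_mean /= cfg.n_iter
    return q_mean, q_samples[:stored], lnl, p_mean, alpha_sum / cfg.n_iter


def _align(reference: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Greedy bijective cluster matching of `other`'s columns onto
    `reference`'s, by total shared ancestry mass."""
    K = reference.shape[1]
    overlap = reference.T @ other
    perm = np.full(K, -1)
    used_r, used_c = set(), set()
    for _ in range(K):
        best = None
        for r in range(K):
            if r in used_r:
                continue
            for c in range(K):
                if c in used_c:
                    continue
                if best is None or overlap[r, c] > overlap[best]:
                    best = (r, c)
        r, c = best
        perm[r] = c
        used_r.add(r)
        used_c.add(c)
    return perm


def run_admixture_mcmc(gm: GenotypeMatrix, cfg: AdmixtureConfig) -> AdmixtureResult:
    """Run the admixture Gibbs sampler and summarise the posterior.

    Chains beyond the first are aligned to it by greedy bijective matching of
    mean ancestry columns (label switching); with ``use_popinfo`` clusters are
    identified by the flagged reference groups directly. 90% credible
    intervals are empirical quantiles of the thinned, pooled Q samples.
    """
    G, valid = _encode(gm)
    n_poly = sum(len(loc.alleles) > 1 for loc in gm.loci)
    if n_poly < 2 and cfg.K > 1:
        raise ValueError("need at least 2 polymorphic loci")
    patterns = {tuple(row.ravel()) for row in gm.calls}
    if cfg.K > len(patterns):
        warnings.warn(f"K={cfg.K} exceeds the {len(patterns)} distinct "
                      "multilocus genotype patterns")
    if cfg.use_popinfo:
        fixed, labels = _popinfo_assignments(gm, cfg.K)
        labels = labels + [f"cluster{j+1}" for j in range(len(labels), cfg.K)]
    else:
        fixed = np.full(gm.n_individuals, -1, dtype=np.int64)
        labels = [f"cluster{j+1}" for j in range(cfg.K)]

    master = np.random.default_rng(cfg.seed)
    chain_seeds = master.integers(0, 2 ** 31 - 1, size=cfg.n_chains)
    q_means, samples, lnls, p_means, alphas = [], [], [], [], []
    for s in chain_seeds:
        qm, qs, lnl, pm, am = _run_chain(G, valid, cfg, fixed,
                                         np.random.default_rng(int(s)))
        q_means.append(qm)
        samples.append(qs)
        lnls.append(lnl)
        p_means.append(pm)
        alphas.append(am)

    if not cfg.use_popinfo and cfg.K > 1:
        for c in range(1, cfg.n_chains):
            perm = _align(q_means[0], q_means[c])
            q_means[c] = q_means[c][:, perm]
            samples[c] = samples[c][:, :, perm]
            p_means[c] = p_means[c][perm]

    q = np.mean(q_means, axis=0)
    pooled = np.concatenate(samples, axis=0)
    lo = np.quantile(pooled, 0.05, axis=0)
    hi = np.quantile(pooled, 0.95, axis=0)
    ids = [ind.id for ind in gm.individuals]
    lnpd = [estimate_lnpd(t) for t in lnls]
    return AdmixtureResult(
        q=pd.DataFrame(q, index=ids, columns=labels),
        ci_lower=pd.DataFrame(np.minimum(lo, q), index=ids, columns=labels),
        ci_upper=pd.DataFrame(np.maximum(hi, q), index=ids, columns=labels),
        lnpd=lnpd,
        cluster_freqs=np.mean(p_means, axis=0),
        cluster_labels=labels,
        config=cfg,
        lnl_traces=lnls,
        q_samples=pooled,
        alpha_mean=alphas,
    )


def estimate_lnpd(trace: np.ndarray) -> float:
    """Model log-evidence estimate ``mean(lnL) - var(lnL)/2`` over retained
    sweeps (the estimator the classic clustering software reports)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 100:
        raise ValueError("need >= 100 post-burn-in samples")
    if not np.isfinite(trace).all():
        raise ValueError("non-finite log-likelihood in trace")
    return float(trace.mean() - trace.var() / 2.0)


@dataclass
class KSelection:
    ks: list[int]
    mean_lnpd: dict[int, float]
    sd_lnpd: dict[int, float]
    delta_k: dict[int, float]

    @property
    def best_k(self) -> int:
        return max(self.delta_k, key=self.delta_k.get)


def delta_k(lnpd_by_k: dict[int, list[float]]) -> KSelection:
    """Evanno-style Delta K: ``|L(K+1) - 2 L(K) + L(K-1)| / sd(L(K))`` for
    each interior K, from >= 2 chains per K."""
    ks = sorted(lnpd_by_k)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be consecutive")
    for k in ks:
        if len(lnpd_by_k[k]) < 2:
            raise ValueError(f"K={k}: need >= 2 chains")
    mean = {k: float(np.mean(lnpd_by_k[k])) for k in ks}
    sd = {k: float(np.std(lnpd_by_k[k], ddof=1)) for k in ks}
    dk: dict[int, float] = {}
    for k in ks[1:-1]:
        num = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
        if sd[k] == 0:
            warnings.warn(f"K={k}: zero sd across chains; Delta K infinite")
            dk[k] = float("inf")
        else:
            dk[k] = num / sd[k]
    return KSelection(ks, mean, sd, dk)


def credible_intervals(q_samples: np.ndarray, level: float = 0.90
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual, per-cluster empirical credible bounds from stored
    ancestry samples of shape (draws, N, K)."""
    if q_samples.shape[0] < 1:
        raise ValueError("no stored samples")
    tail = (1.0 - level) / 2.0
    return (np.quantile(q_samples, tail, axis=0),
            np.quantile(q_samples, 1.0 - tail, axis=0))
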