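"""Within-group diversity: heterozygosity, private alleles, Hardy-Weinberg
and linkage permutation tests, and probability-of-identity panels.

Significance is assessed by Monte Carlo permutation rather than asymptotic
chi-square, matching standard practice for microsatellite data where many
genotype cells are sparse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import MISSING, AlleleFrequencyTable, GenotypeMatrix, allele_frequencies


@dataclass
class DiversitySummary:
    group: str
    n: int
    na: float                 # mean alleles per locus
    np_private: int           # private alleles vs all other groups
    ho: float
    uhe: float
    pid: float
    pid_sibs: float
    fis: float | None = None
    fis_p: float | None = None
    pct_le: float | None = None


def _locus_stats(gm: GenotypeMatrix, mask: np.ndarray, j: int
                 ) -> tuple[int, float, float, np.ndarray, np.ndarray] | None:
    """Per-locus (n_genotyped, Ho, UHe, allele labels, freqs) within a group;
    None when no complete genotypes are available."""
    calls = gm.calls[mask, j, :]
    complete = (calls != MISSING).all(axis=1)
    calls = calls[complete]
    if calls.shape[0] == 0:
        return None
    n = calls.shape[0]
    ho = float((calls[:, 0] != calls[:, 1]).mean())
    labels, counts = np.unique(calls.ravel(), return_counts=True)
    p = counts / counts.sum()
    two_n = 2 * n
    uhe = 0.0 if two_n < 2 else (two_n / (two_n - 1)) * (1.0 - float((p ** 2).sum()))
    return n, ho, uhe, labels, p


def diversity_summary(gm: GenotypeMatrix, group: str) -> DiversitySummary:
    """Mean alleles/locus, private alleles, Ho, unbiased He and PID values
    for one group, averaged over loci with data.

    Unbiased expected heterozygosity per locus is
    ``(2N/(2N-1)) * (1 - sum p_i^2)``; private alleles are those absent from
    every other group in the dataset.
    """
    mask = gm.group_mask(group)
    if mask.sum() < 2:
        raise ValueError(f"group {group!r} needs at least 2 individuals")
    freqs = allele_frequencies(gm)
    nas, hos, uhes = [], [], []
    for j, locus in enumerate(gm.loci):
        stats = _locus_stats(gm, mask, j)
        if stats is None:
            warnings.warn(f"locus {locus.name} undefined in {group}; skipped")
            continue
        _, ho, uhe, labels, _ = stats
        nas.append(len(labels))
        hos.append(ho)
        uhes.append(uhe)
    n_private = 0
    others = [g for g in gm.groups if g != group]
    for locus in gm.loci:
        mine = set(freqs.freqs[group].get(locus.name, {}))
        theirs: set[int] = set()
        for g in others:
            theirs |= set(freqs.freqs[g].get(locus.name, {}))
        n_private += len(mine - theirs)
    panel = gm.locus_names
    return DiversitySummary(
        group=group,
        n=int(mask.sum()),
        na=float(np.mean(nas)) if nas else float("nan"),
        np_private=n_private,
        ho=float(np.mean(hos)) if hos else float("nan"),
        uhe=float(np.mean(uhes)) if uhes else float("nan"),
        pid=pid_unrelated(freqs, group, panel),
        pid_sibs=pid_sibs(freqs, group, panel),
    )


# -- F_IS / HWE ----------------------------------------------------------------


def _multilocus_fis(gm: GenotypeMatrix, mask: np.ndarray) -> float:
    """Multilocus F_IS = 1 - Ho/UHe with loci weighted by genotyped sample."""
    num = den = 0.0
    for j in range(gm.n_loci):
        stats = _locus_stats(gm, mask, j)
        if stats is None:
            continue
        n, ho, uhe, _, _ = stats
        num += n * ho
        den += n * uhe
    if den == 0:
        raise ValueError("all loci monomorphic: F_IS undefined")
    return 1.0 - num / den


def fis_hwe_test(gm: GenotypeMatrix, group: str, n_perm: int = 1000,
                 seed: int = 0) -> tuple[float, float]:
    """Multilocus F_IS with a Hardy-Weinberg permutation p-value.

    The null is built by shuffling allele copies among individuals within
    each locus (which enforces random union of gametes while preserving
    allele frequencies); p is the fraction of replicates with
    ``|F_IS| >= |observed|``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    mask = gm.group_mask(group)
    observed = _multilocus_fis(gm, mask)
    rng = np.random.default_rng(seed)
    sub = gm.calls[mask].copy()
    n_extreme = 0
    for _ in range(n_perm):
        perm = sub.copy()
        for j in range(gm.n_loci):
            copies = perm[:, j, :].ravel()
            obs_idx = np.flatnonzero(copies != MISSING)
            shuffled = copies[obs_idx]
            rng.shuffle(shuffled)
            copies[obs_idx] = shuffled
            perm[:, j, :] = copies.reshape(-1, 2)
        gm_like = _FisView(perm)
        try:
            f = _multilocus_fis(gm_like, np.ones(perm.shape[0], dtype=bool))
        except ValueError:
            continue
        if abs(f) >= abs(observed):
            n_extreme += 1
    p = (n_extreme + 1) / (n_perm + 1)
    return observed, p


class _FisView:
    """Minimal duck-typed stand-in exposing .calls/.n_loci for permuted data."""

    def __init__(self, calls: np.ndarray):
        self.calls = calls
        self.n_loci = calls.shape[1]


# -- pairwise linkage test -----------------------------------------------------


def _g_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Log-likelihood-ratio (G) statistic of the two-locus genotype table."""
    xs, xi = np.unique(x, return_inverse=True)
    ys, yi = np.unique(y, return_inverse=True)
    table = np.zeros((len(xs), len(ys)))
    np.add.at(table, (xi, yi), 1.0)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return 2.0 * float(terms.sum())


def ld_pairwise_test(gm: GenotypeMatrix, group: str, n_perm: int = 1000,
                     alpha: float = 0.05, seed: int = 0
                     ) -> tuple[float, dict[tuple[str, str], float]]:
    """Permutation test of genotypic linkage equilibrium for every locus pair.

    One locus's genotypes are shuffled across individuals to build the null
    of the G statistic; significance uses Bonferroni correction over the
    tested pairs. Returns (percent significant pairs, per-pair p-values).
    Pairs with fewer than 5 jointly genotyped individuals are excluded.
    """
    mask = gm.group_mask(group)
    calls = gm.calls[mask]
    # genotype code per individual x locus, -1 when incomplete
    lo = np.sort(calls, axis=2)
    poly = []
    codes = np.full(calls.shape[:2], -1, dtype=np.int64)
    for j in range(gm.n_loci):
        complete = (calls[:, j, :] != MISSING).all(axis=1)
        pairs = lo[complete, j, 0] * 100000 + lo[complete, j, 1]
        _, inv = np.unique(pairs, return_inverse=True)
        codes[complete, j] = inv
        copies = calls[complete, j, :].ravel()
        if complete.any() and np.unique(copies).size > 1:
            poly.append(j)
    if len(poly) < 2:
        raise ValueError("need at least 2 polymorphic loci for a linkage test")
    rng = np.random.default_rng(seed)
    pvals: dict[tuple[str, str], float] = {}
    for a_idx in range(len(poly)):
        for b_idx in range(a_idx + 1, len(poly)):
            ja, jb = poly[a_idx], poly[b_idx]
            ok = (codes[:, ja] >= 0) & (codes[:, jb] >= 0)
            if ok.sum() < 5:
                continue
            x, y = codes[ok, ja], codes[ok, jb]
            obs = _g_statistic(x, y)
            hits = 0
            for _ in range(n_perm):
                if _g_statistic(x, rng.permutation(y)) >= obs:
                    hits += 1
            pvals[(gm.loci[ja].name, gm.loci[jb].name)] = (hits + 1) / (n_perm + 1)
    if not pvals:
        raise ValueError("no informative locus pairs")
    cutoff = alpha / len(pvals)  # Bonferroni over the locus-pair family
    pct = 100.0 * np.mean([p <= cutoff for p in pvals.values()])
    return float(pct), pvals


# -- probability of identity ---------------------------------------------------


def pid_unrelated(freqs: AlleleFrequencyTable, group: str,
                  panel: list[str]) -> float:
    """Probability that two unrelated individuals share a multilocus genotype:
    per locus ``2 (sum p^2)^2 - sum p^4``, multiplied across the panel."""
    out = 1.0
    for name in panel:
        p = np.array(list(freqs.vector(group, name).values()))
        if p.size == 0:
            raise ValueError(f"no frequency data for {group} x {name}")
        s2, s4 = float((p ** 2).sum()), float((p ** 4).sum())
        out *= 2 * s2 ** 2 - s4
    return out


def pid_sibs(freqs: AlleleFrequencyTable, group: str, panel: list[str]) -> float:
    """Probability of identity among full siblings:
    per locus ``0.25 + 0.5 sum p^2 + 0.5 (sum p^2)^2 - 0.25 sum p^4``."""
    out = 1.0
    for name in panel:
        p = np.array(list(freqs.vector(group, name).values()))
        if p.size == 0:
            raise ValueError(f"no frequency data for {group} x {name}")
        s2, s4 = float((p ** 2).sum()), float((p ** 4).sum())
        out *= 0.25 + 0.5 * s2 + 0.5 * s2 ** 2 - 0.25 * s4
    return out
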