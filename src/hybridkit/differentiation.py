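"""Population differentiation: the Weir-Cockerham variance-components
estimator of F_ST (theta) and a one-level AMOVA Phi-PT on a distance matrix.

The multilocus theta pools variance components across loci and alleles
(ratio of sums), never a mean of per-locus ratios; this is the convention of
the original estimator and what the widely used software reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix


@dataclass
class DifferentiationResult:
    groups: list[str]
    per_locus: dict[str, float] = field(default_factory=dict)
    overall: float | None = None
    pairwise: "np.ndarray | None" = None  # groups x groups multilocus theta
    phi_pt: float | None = None
    phi_pt_p: float | None = None


def _wc_components(gm: GenotypeMatrix, masks: list[np.ndarray], j: int
                   ) -> tuple[float, float, float] | None:
    """Summed (a, b, c) variance components over alleles at locus j, or None
    if fewer than two groups have data or the locus is monomorphic overall."""
    ns, ps, hs, labels_all = [], [], [], set()
    per_group = []
    for mask in masks:
        calls = gm.calls[mask, j, :]
        complete = (calls != MISSING).all(axis=1)
        calls = calls[complete]
        if calls.shape[0] == 0:
            continue
        per_group.append(calls)
        labels_all |= set(calls.ravel().tolist())
    if len(per_group) < 2 or len(labels_all) < 2:
        return None
    labels = sorted(labels_all)
    r = len(per_group)
    n_i = np.array([c.shape[0] for c in per_group], dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    if nbar <= 1 or nc <= 0:
        return None
    a_sum = b_sum = c_sum = 0.0
    for allele in labels:
        p_i = np.array([(c == allele).mean() for c in per_group])
        h_i = np.array([
            ((c[:, 0] != c[:, 1]) & ((c == allele).any(axis=1))).mean()
            for c in per_group
        ])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (
                pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0
            )
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        a_sum, b_sum, c_sum = a_sum + a, b_sum + b, c_sum + c
    return a_sum, b_sum, c_sum


def weir_cockerham_theta(gm: GenotypeMatrix,
                         groups: list[str] | None = None,
                         scope: str = "multilocus"):
    """Weir-Cockerham theta between the named groups.

    scope:
        ``per_locus`` — dict locus name -> theta_l (NaN where undefined);
        ``multilocus`` — single pooled estimate (ratio of summed components);
        ``pairwise_matrix`` — DifferentiationResult with a groups x groups
        multilocus matrix.

    Loci monomorphic across all contributing groups are excluded from sums.
    """
    groups = groups or gm.groups
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if scope == "pairwise_matrix":
        k = len(groups)
        mat = np.full((k, k), 0.0)
        for i in range(k):
            for j in range(i + 1, k):
                sub = weir_cockerham_theta(gm, [groups[i], groups[j]],
                                           scope="multilocus")
                mat[i, j] = mat[j, i] = sub
        res = DifferentiationResult(groups=list(groups))
        res.pairwise = mat
        return res
    masks = [gm.group_mask(g) for g in groups]
    for g, m in zip(groups, masks):
        if m.sum() < 2:
            raise ValueError(f"group {g!r} needs >= 2 individuals")
    per_locus: dict[str, float] = {}
    a_tot = d_tot = 0.0
    for j, locus in enumerate(gm.loci):
        comp = _wc_components(gm, masks, j)
        if comp is None:
            per_locus[locus.name] = float("nan")
            continue
        a, b, c = comp
        denom = a + b + c
        per_locus[locus.name] = a / denom if denom != 0 else float("nan")
        a_tot += a
        d_tot += denom
    if scope == "per_locus":
        return per_locus
    if scope == "multilocus":
        if d_tot == 0:
            raise ValueError("theta undefined: no polymorphic loci")
        return a_tot / d_tot
    raise ValueError(f"unknown scope {scope!r}")


# -- AMOVA Phi-PT ---------------------------------------------------------------


def _phi_from_labels(d2: np.ndarray, codes: np.ndarray) -> float:
    """One-level AMOVA Phi-PT from a squared-distance matrix and group codes."""
    n = d2.shape[0]
    groups = np.unique(codes)
    g = len(groups)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    sizes = []
    for grp in groups:
        idx = np.flatnonzero(codes == grp)
        sizes.append(len(idx))
        if len(idx) > 1:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    sizes_arr = np.array(sizes, dtype=float)
    ss_among = ss_total - ss_within
    df_among, df_within = g - 1, n - g
    if df_within == 0:
        return float("nan")
    n0 = (n - (sizes_arr ** 2).sum() / n) / df_among
    var_within = ss_within / df_within
    var_among = (ss_among / df_among - var_within) / n0
    denom = var_among + var_within
    return float(var_among / denom) if denom > 0 else 0.0


def amova_phipt(distances: np.ndarray, groups: list[str], n_perm: int = 999,
                seed: int = 0) -> tuple[float, float]:
    """Phi-PT (among-group fraction of squared-distance variance) with a
    label-permutation p-value.

    ``distances`` must be a symmetric non-negative matrix with zero diagonal
    of *plain* distances; squaring happens internally. Groups of size 1 are
    allowed (they contribute no within-group sum) but make the estimate
    fragile.
    """
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if (np.diag(d) != 0).any() or (d < 0).any():
        raise ValueError("distances must be non-negative with zero diagonal")
    _, codes = np.unique(np.asarray(groups), return_inverse=True)
    if codes.size != d.shape[0]:
        raise ValueError("group labels do not match matrix size")
    d2 = d ** 2
    observed = _phi_from_labels(d2, codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _phi_from_labels(d2, rng.permutation(codes)) >= observed:
            hits += 1
    return observed, (hits + 1) / (n_perm + 1)


def allele_count_distances(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise Euclidean distance on per-individual allele-count vectors,
    the genotypic distance used for Phi-PT on STR data."""
    offsets = np.cumsum([0] + [len(loc.alleles) for loc in gm.loci])
    width = offsets[-1]
    counts = np.zeros((gm.n_individuals, width))
    for j, locus in enumerate(gm.loci):
        index = {a: k for k, a in enumerate(locus.alleles)}
        for i in range(gm.n_individuals):
            for copy in gm.calls[i, j]:
                if copy != MISSING:
                    counts[i, offsets[j] + index[int(copy)]] += 1
    diff = counts[:, None, :] - counts[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def mismatch_distances(haplotypes: list[str]) -> np.ndarray:
    """0/1 haplotype mismatch distance for uniparental markers."""
    arr = np.asarray(haplotypes, dtype=object)
    return (arr[:, None] != arr[None, :]).astype(float)
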