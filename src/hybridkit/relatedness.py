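"""Queller-Goodnight pairwise relatedness from reference allele frequencies."""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from .core import MISSING, AlleleFrequencyTable, GenotypeMatrix


def _pair_components(gm: GenotypeMatrix, i: int, k: int,
                     ref: AlleleFrequencyTable, ref_group: str
                     ) -> tuple[float, float]:
    """Summed numerator/denominator over loci for the symmetric estimator,
    averaging the two choices of focal individual."""
    num = den = 0.0
    for j, locus in enumerate(gm.loci):
        gx, gy = gm.calls[i, j], gm.calls[k, j]
        if (gx == MISSING).any() or (gy == MISSING).any():
            continue
        vec = ref.freqs[ref_group].get(locus.name)
        if not vec:
            continue
        for (a, b), (c, d) in ((gx, gy), (gy, gx)):
            pa, pb = vec.get(int(a), 0.0), vec.get(int(b), 0.0)
            share = 0.5 * (int(a == c) + int(a == d) + int(b == c) + int(b == d))
            num += share - pa - pb
            den += 1.0 + int(a == b) - pa - pb
    return num, den


def queller_goodnight_r(gm: GenotypeMatrix, individuals: list[str],
                        ref_freqs: AlleleFrequencyTable,
                        ref_group: str) -> float | np.ndarray:
    """Symmetric Queller-Goodnight relatedness.

    For a pair, components are summed over loci before taking the ratio and
    both individuals serve as focal; for a set of >2 individuals the mean of
    all pairwise values is returned together with the pair matrix.
    """
    idx = {ind.id: i for i, ind in enumerate(gm.individuals)}
    try:
        rows = [idx[name] for name in individuals]
    except KeyError as exc:
        raise KeyError(f"unknown individual {exc.args[0]!r}") from None
    if len(rows) < 2:
        raise ValueError("need at least two individuals")
    if len(rows) == 2:
        num, den = _pair_components(gm, rows[0], rows[1], ref_freqs, ref_group)
        if den == 0:
            raise ValueError("relatedness undefined: zero denominator at all loci")
        return num / den
    vals = []
    for i, k in itertools.combinations(rows, 2):
        num, den = _pair_components(gm, i, k, ref_freqs, ref_group)
        vals.append(num / den if den != 0 else np.nan)
    return np.array(vals)


def relatedness_t_test(r_a: np.ndarray, r_b: np.ndarray) -> tuple[float, float]:
    """Welch t-test comparing two sets of pairwise relatedness values.

    Pairwise r values sharing individuals are not independent, so the p-value
    is indicative rather than exact; it mirrors the field's common usage.
    """
    t, p = stats.ttest_ind(np.asarray(r_a), np.asarray(r_b), equal_var=False)
    return float(t), float(p)
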