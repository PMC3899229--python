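"""Ranking loci by wolf-dog discriminating power and building nested panels.

Loci are ranked by per-locus theta between the two reference groups; the
allele-frequency differential and a greedy assignment-based selection serve
as confirmatory criteria, with a consistency report flagging loci whose
ranks disagree badly across criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classify import rannala_mountain_score
from .core import AlleleFrequencyTable, GenotypeMatrix, allele_frequencies
from .differentiation import weir_cockerham_theta


@dataclass
class LocusScore:
    locus: str
    theta: float
    delta: float
    assign_gain: float | None = None
    rank_theta: int | None = None
    rank_delta: int | None = None
    rank_assign: int | None = None


@dataclass
class PanelRanking:
    ranked: list[LocusScore]
    panels: dict[str, list[str]] = field(default_factory=dict)
    panel_theta: dict[str, float] = field(default_factory=dict)

    @property
    def order(self) -> list[str]:
        return [s.locus for s in self.ranked]


def allele_freq_differential(freqs: AlleleFrequencyTable, group_a: str,
                             group_b: str, locus: str) -> float:
    """delta = 0.5 * sum_a |p_A(a) - p_B(a)| over the union of alleles."""
    va = freqs.vector(group_a, locus)
    vb = freqs.vector(group_b, locus)
    if not va or not vb:
        raise ValueError(f"locus {locus}: frequencies undefined in a group")
    alleles = set(va) | set(vb)
    return 0.5 * sum(abs(va.get(a, 0.0) - vb.get(a, 0.0)) for a in alleles)


def rank_by_fst(gm: GenotypeMatrix, group_a: str, group_b: str
                ) -> list[LocusScore]:
    """Descending per-locus theta ranking between two reference groups; ties
    broken by the allele-frequency differential, then locus name. Loci with
    undefined theta (monomorphic in both) sort last."""
    per_locus = weir_cockerham_theta(gm, [group_a, group_b], scope="per_locus")
    freqs = allele_frequencies(gm, [group_a, group_b])
    scores = []
    for name, th in per_locus.items():
        try:
            delta = allele_freq_differential(freqs, group_a, group_b, name)
        except ValueError:
            delta = 0.0
        scores.append(LocusScore(name, float(th), float(delta)))
    scores.sort(key=lambda s: (np.isnan(s.theta), -(s.theta if not np.isnan(s.theta) else 0.0),
                               -s.delta, s.locus))
    for r, s in enumerate(scores, 1):
        s.rank_theta = r
    by_delta = sorted(scores, key=lambda s: (-s.delta, s.locus))
    for r, s in enumerate(by_delta, 1):
        s.rank_delta = r
    return scores


def assignment_based_score(gm: GenotypeMatrix, group_a: str, group_b: str,
                           seed: int = 0, max_loci: int | None = None
                           ) -> list[LocusScore]:
    """Greedy forward selection by leave-one-out self-assignment accuracy.

    At each step the locus that most improves two-group LOO self-assignment
    (posterior-predictive likelihood assignment) joins the panel; its
    ``assign_gain`` is the accuracy increment at inclusion. When accuracy
    plateaus, the remaining loci are appended in theta order.
    """
    for g in (group_a, group_b):
        if gm.group_mask(g).sum() < 10:
            warnings.warn(f"group {g}: fewer than 10 individuals; "
                          "assignment ranking will be noisy")
    base = rank_by_fst(gm, group_a, group_b)
    theta_order = [s.locus for s in base]
    members = gm.subset_individuals(
        np.array([ind.group in (group_a, group_b) for ind in gm.individuals]))
    remaining = list(gm.locus_names)
    chosen: list[str] = []
    scores: list[LocusScore] = []
    acc = 0.5
    limit = max_loci or len(remaining)
    theta_by_name = {s.locus: s for s in base}
    while remaining and len(chosen) < limit:
        best_locus, best_acc = None, -1.0
        for name in remaining:
            a = _loo_accuracy(members, group_a, group_b, chosen + [name])
        # evaluate all candidates, keep the best (ties -> theta order)
            if a > best_acc + 1e-12:
                best_locus, best_acc = name, a
        if best_acc <= acc + 1e-12:
            break  # plateau
        chosen.append(best_locus)
        remaining.remove(best_locus)
        src = theta_by_name[best_locus]
        scores.append(LocusScore(best_locus, src.theta, src.delta,
                                 assign_gain=best_acc - acc))
        acc = best_acc
    for name in sorted(remaining, key=theta_order.index):
        src = theta_by_name[name]
        scores.append(LocusScore(name, src.theta, src.delta, assign_gain=0.0))
    for r, s in enumerate(scores, 1):
        s.rank_assign = r
    return scores


def _loo_accuracy(gm: GenotypeMatrix, group_a: str, group_b: str,
                  loci: list[str]) -> float:
    sub = gm.subset_loci(loci)
    hits = 0
    for ind in sub.individuals:
        score = rannala_mountain_score(sub, ind.id, [group_a, group_b])
        hits += score.best_group == ind.group
    return hits / sub.n_individuals


def build_panels(gm: GenotypeMatrix, ranking: list[LocusScore],
                 sizes: list[int], group_a: str, group_b: str,
                 legacy: dict[str, list[str]] | None = None) -> PanelRanking:
    """Nested prefix panels of the requested sizes plus optional named legacy
    panels kept verbatim, each annotated with its multilocus theta."""
    order = [s.locus for s in ranking]
    pr = PanelRanking(ranked=list(ranking))
    for size in sorted(set(sizes), reverse=True):
        if size > len(order):
            raise ValueError(f"panel size {size} exceeds {len(order)} ranked loci")
        name = f"top{size}"
        pr.panels[name] = order[:size]
    pr.panels["full"] = list(order)
    for name, loci in (legacy or {}).items():
        missing = set(loci) - set(gm.locus_names)
        if missing:
            raise ValueError(f"legacy panel {name}: unknown loci {sorted(missing)}")
        pr.panels[name] = list(loci)
    for name, loci in pr.panels.items():
        sub = gm.subset_loci(loci)
        pr.panel_theta[name] = float(
            weir_cockerham_theta(sub, [group_a, group_b]))
    return pr


def consistency_report(ranking: list[LocusScore]) -> list[str]:
    """Loci whose delta- or assignment-rank differs from the theta rank by
    more than a quarter of the panel (criteria disagree on them)."""
    L = len(ranking)
    flagged = []
    for s in ranking:
        for other in (s.rank_delta, s.rank_assign):
            if other is not None and s.rank_theta is not None \
                    and abs(other - s.rank_theta) > L / 4:
                flagged.append(s.locus)
                break
    return flagged
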