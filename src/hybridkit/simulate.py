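"""Synthetic parental populations and hybrid-class genotype simulation.

Two parental microsatellite populations are generated under the
Balding-Nichols model: ancestral allele frequencies come from a symmetric
Dirichlet and each population's frequencies from
``Dirichlet(p_anc * (1-F)/F)``, with the drift parameter of each population
set from its heterozygosity target and the ancestral diversity dial tuned so
the realized multilocus theta hits the requested divergence. Hybrid classes
are then built the way HybridLab does: every offspring allele is an
independent draw from a parental pool's allele-frequency distribution, so
family structure within a pool is deliberately ignored.

Default study conditions follow the wolf x dog design this toolkit was
built around: 39 loci, wolf-side Ho 0.46, dog-side Ho 0.71, multilocus
theta 0.25, and 60 simulated genotypes per hybrid class.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix, IndividualMeta, Locus
from .differentiation import weir_cockerham_theta


class HybridClass(enum.Enum):
    P_W = "P_W"
    P_D = "P_D"
    F1 = "F1"
    F2 = "F2"
    BC1W = "BC1W"
    BC1D = "BC1D"
    BC2W = "BC2W"
    BC2D = "BC2D"
    BC3W = "BC3W"
    BC3D = "BC3D"


_EXPECTED_W_FRACTION = {
    HybridClass.P_W: 1.0,
    HybridClass.P_D: 0.0,
    HybridClass.F1: 0.5,
    HybridClass.F2: 0.5,
    HybridClass.BC1W: 0.75,
    HybridClass.BC1D: 0.25,
    HybridClass.BC2W: 0.875,
    HybridClass.BC2D: 0.125,
    HybridClass.BC3W: 0.9375,
    HybridClass.BC3D: 0.0625,
}


def expected_ancestry(cls: HybridClass) -> float:
    """Expected fraction of the genome inherited from the W parental pool."""
    return _EXPECTED_W_FRACTION[HybridClass(cls)]


@dataclass
class SyntheticPopSpec:
    """Study conditions for the two-parental-population generator."""

    n_loci: int = 39
    alleles_per_locus: int = 12
    target_fst: float = 0.25
    target_ho: dict[str, float] = field(
        default_factory=lambda: {"W": 0.46, "D": 0.71})
    n_individuals: dict[str, int] = field(
        default_factory=lambda: {"W": 60, "D": 60})
    seed: int = 0
    fst_tolerance: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 < self.target_fst < 1.0:
            raise ValueError("target_fst must be in (0, 1)")
        if set(self.target_ho) != set(self.n_individuals):
            raise ValueError("target_ho and n_individuals must name the same pops")
        for pop, n in self.n_individuals.items():
            if n < 2:
                raise ValueError(f"population {pop}: need >= 2 individuals")
        he_max = 1.0 - 1.0 / self.alleles_per_locus
        for pop, ho in self.target_ho.items():
            if ho >= 0.98 * he_max:
                raise ValueError(
                    f"population {pop}: Ho target {ho} infeasible with "
                    f"{self.alleles_per_locus} alleles (max He {he_max:.2f})"
                )


def _thin_to_target_he(rng: np.random.Generator, freqs: np.ndarray,
                       target_he: float) -> np.ndarray:
    """Reduce allele richness until the mean expected heterozygosity across
    loci reaches the target.

    Repeatedly removes the rarest allele of the currently most heterozygous
    locus (frequencies renormalised), which mimics the loss of rare alleles
    in a bottlenecked population and creates hard allele absences — the
    private alleles that make real parental populations assignable."""
    f = freqs.copy()

    def he(row: np.ndarray) -> float:
        return 1.0 - float((row ** 2).sum())

    hes = np.array([he(row) for row in f])
    while hes.mean() > target_he:
        # thin a random locus, preferring those far above target, so the
        # per-locus heterozygosity spread stays realistic
        excess = np.maximum(hes - target_he, 0.0)
        thinnable = np.array([(row > 0).sum() > 2 for row in f])
        weights = excess * thinnable
        if weights.sum() == 0:
            break
        l = int(rng.choice(len(f), p=weights / weights.sum()))
        row = f[l]
        alive = np.flatnonzero(row > 0)
        drop = alive[np.argmin(row[alive])]
        row[drop] = 0.0
        row /= row.sum()
        hes[l] = he(row)
    return f


def _draw_pop_freqs(rng: np.random.Generator, drift: float,
                    spec: SyntheticPopSpec,
                    p_anc: np.ndarray) -> dict[str, np.ndarray]:
    """One draw of per-population frequency arrays (pop -> L x A): a common
    Balding-Nichols drift parameter, then per-population richness thinning
    to the heterozygosity target."""
    scale = (1.0 - drift) / drift
    out = {}
    for pop, ho in spec.target_ho.items():
        freqs = np.empty_like(p_anc)
        for l in range(spec.n_loci):
            freqs[l] = rng.dirichlet(np.maximum(p_anc[l] * scale, 1e-6))
        out[pop] = _thin_to_target_he(rng, freqs, ho)
    return out


def _genotypes_from_freqs(rng: np.random.Generator, freqs: np.ndarray,
                          n: int) -> np.ndarray:
    """(n, L, 2) HWE genotype draw; allele labels are 1-based columns."""
    L, A = freqs.shape
    cum = freqs.cumsum(axis=1)
    u = rng.random((n, L, 2))
    return (u[..., None] > cum[None, :, None, :]).sum(axis=3) + 1


def _matrix_from_calls(calls_by_pop: dict[str, np.ndarray],
                       n_alleles: int, popflag: bool = False) -> GenotypeMatrix:
    loci = [Locus(f"L{j+1:03d}", tuple(range(1, n_alleles + 1)))
            for j in range(next(iter(calls_by_pop.values())).shape[1])]
    individuals, rows = [], []
    for pop, calls in calls_by_pop.items():
        for i in range(calls.shape[0]):
            individuals.append(IndividualMeta(id=f"{pop}_{i+1:03d}", group=pop,
                                              popflag=popflag))
            rows.append(calls[i])
    return GenotypeMatrix(individuals, loci, np.stack(rows))


def simulate_parental_pops(spec: SyntheticPopSpec) -> GenotypeMatrix:
    """Generate two diverged parental populations matching the spec's
    heterozygosity and divergence targets.

    The ancestral Dirichlet concentration is tuned by bisection on the
    realized multilocus theta of a fresh genotype draw; candidate draws are
    accepted only when theta lands within ``fst_tolerance`` of the target,
    so the returned dataset always satisfies the calibration. Deterministic
    for a fixed spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    # ancestral diversity must exceed the highest Ho target; a unit Dirichlet
    # over the allele set gives He_anc ~ 0.8 with the default 10 alleles
    p_anc = rng.dirichlet(np.full(spec.alleles_per_locus, 1.0),
                          size=spec.n_loci)
    lo, hi = 0.003, 0.8
    best = None
    for _ in range(40):
        drift = 0.5 * (lo + hi)
        freqs = _draw_pop_freqs(rng, drift, spec, p_anc)
        calls = {pop: _genotypes_from_freqs(rng, freqs[pop], n)
                 for pop, n in spec.n_individuals.items()}
        gm = _matrix_from_calls(calls, spec.alleles_per_locus)
        theta = weir_cockerham_theta(gm, list(spec.n_individuals))
        if abs(theta - spec.target_fst) <= spec.fst_tolerance:
            best = gm
            break
        if theta < spec.target_fst:
            lo = drift
        else:
            hi = drift
    if best is None:
        raise RuntimeError(
            "could not calibrate divergence: the Ho/theta combination appears "
            "infeasible for this allele richness"
        )
    for pop, ho_target in spec.target_ho.items():
        calls = best.calls[best.group_mask(pop)]
        ho = float((calls[:, :, 0] != calls[:, :, 1]).mean())
        if abs(ho - ho_target) > 0.05:
            warnings.warn(
                f"population {pop}: realized Ho {ho:.3f} misses target "
                f"{ho_target:.2f} by more than 0.05"
            )
    return best


# -- HybridLab-style crossing ---------------------------------------------------


def _pool_freqs(pool: GenotypeMatrix) -> np.ndarray:
    """Per-locus allele frequencies (L x A over the locus allele sets) of a
    genotype pool; errors on a locus with no data."""
    amax = max(len(loc.alleles) for loc in pool.loci)
    freqs = np.zeros((pool.n_loci, amax))
    for j, locus in enumerate(pool.loci):
        copies = pool.calls[:, j, :].ravel()
        copies = copies[copies != MISSING]
        if copies.size == 0:
            raise ValueError(f"locus {locus.name}: no alleles in pool")
        index = {a: k for k, a in enumerate(locus.alleles)}
        for c in copies:
            freqs[j, index[int(c)]] += 1
        freqs[j] /= freqs[j].sum()
    return freqs


def simulate_cross(pool_a: GenotypeMatrix, pool_b: GenotypeMatrix, n: int,
                   seed: int, group: str = "cross") -> GenotypeMatrix:
    """Draw ``n`` offspring, one allele per locus from each pool's
    allele-frequency distribution, independently across loci."""
    if pool_a.locus_names != pool_b.locus_names:
        raise ValueError("pools must share the same locus panel")
    rng = np.random.default_rng(seed)
    calls = np.empty((n, pool_a.n_loci, 2), dtype=np.int64)
    for src, copy in ((pool_a, 0), (pool_b, 1)):
        freqs = _pool_freqs(src)
        for j, locus in enumerate(src.loci):
            labels = np.array(locus.alleles)
            k = len(labels)
            draws = rng.choice(k, size=n, p=freqs[j, :k])
            calls[:, j, copy] = labels[draws]
    loci = [
        Locus(a.name, tuple(sorted(set(a.alleles) | set(b.alleles))),
              a.chromosome_class)
        for a, b in zip(pool_a.loci, pool_b.loci)
    ]
    individuals = [IndividualMeta(id=f"{group}_{i+1:03d}", group=group)
                   for i in range(n)]
    return GenotypeMatrix(individuals, loci, calls)


@dataclass
class SimPanel:
    """A labelled panel of simulated hybrid-class genotypes."""

    matrix: GenotypeMatrix
    classes: list[HybridClass]
    provenance: dict


def simulate_class_panel(parents_w: GenotypeMatrix, parents_d: GenotypeMatrix,
                         classes: list[HybridClass], n_per_class: int = 60,
                         seed: int = 0, alt_bc3: bool = False) -> SimPanel:
    """Simulate hybrid classes by pedigree composition.

    F1 = W x D; F2 = F1 x F1; BC1W = F1 x W; BC2W = BC1W x W;
    BC3W = BC2W x W (with ``alt_bc3`` instead F2 x W), mirrored on the dog
    side; parental classes are redrawn from their own pool frequencies.
    Intermediate pools have ``n_per_class`` genotypes.
    """
    if n_per_class < 10:
        warnings.warn("n_per_class < 10: pool-frequency noise will be large")
    classes = [HybridClass(c) for c in classes]
    rng = np.random.default_rng(seed)

    def child_seed() -> int:
        return int(rng.integers(0, 2 ** 31 - 1))

    pools: dict[HybridClass, GenotypeMatrix] = {}

    def build(cls: HybridClass) -> GenotypeMatrix:
        if cls in pools:
            return pools[cls]
        W, D = parents_w, parents_d
        recipe = {
            HybridClass.P_W: (W, W),
            HybridClass.P_D: (D, D),
            HybridClass.F1: (W, D),
        }
        if cls in recipe:
            a, b = recipe[cls]
        elif cls == HybridClass.F2:
            a = b = build(HybridClass.F1)
        elif cls == HybridClass.BC1W:
            a, b = build(HybridClass.F1), W
        elif cls == HybridClass.BC1D:
            a, b = build(HybridClass.F1), D
        elif cls == HybridClass.BC2W:
            a, b = build(HybridClass.BC1W), W
        elif cls == HybridClass.BC2D:
            a, b = build(HybridClass.BC1D), D
        elif cls == HybridClass.BC3W:
            a, b = (build(HybridClass.F2), W) if alt_bc3 else (build(HybridClass.BC2W), W)
        elif cls == HybridClass.BC3D:
            a, b = (build(HybridClass.F2), D) if alt_bc3 else (build(HybridClass.BC2D), D)
        else:  # pragma: no cover - enum is closed
            raise ValueError(cls)
        pools[cls] = simulate_cross(a, b, n_per_class, child_seed(), group=cls.value)
        return pools[cls]

    # canonical pedigree order so derived seeds do not depend on the order
    # the caller listed the classes
    ordered = [c for c in HybridClass if c in classes]
    panel: GenotypeMatrix | None = None
    for cls in ordered:
        sub = build(cls)
        panel = sub if panel is None else panel.concat(sub)
    if panel is None:
        raise ValueError("no classes requested")
    return SimPanel(
        matrix=panel,
        classes=ordered,
        provenance={
            "seed": seed,
            "n_per_class": n_per_class,
            "alt_bc3": alt_bc3,
            "parent_pools": {"W": parents_w.n_individuals,
                             "D": parents_d.n_individuals},
        },
    )
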