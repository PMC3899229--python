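"""Core domain types for multilocus STR datasets.

The toolkit operates on diploid microsatellite genotypes collected from
several labelled groups (wolf populations, dog groups, putative hybrids).
Alleles are opaque integer labels: all downstream statistics are
frequency-based, so no repeat-unit (stepwise mutation) arithmetic is ever
performed on them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1  # internal sentinel for a missing allele copy


class ChromosomeClass(enum.Enum):
    AUTOSOMAL = "autosomal"
    Y = "Y"
    MTDNA = "mtDNA"
    K_LOCUS = "K_locus"


class Sex(enum.Enum):
    M = "M"
    F = "F"
    UNKNOWN = "unknown"


class KGenotype(enum.Enum):
    """Genotype at the dominant K-locus (beta-defensin CBD103 melanistic deletion)."""

    WT_WT = "wt_wt"
    KB_WT = "KB_wt"
    KB_KB = "KB_KB"


@dataclass(frozen=True)
class Locus:
    """A named marker with its observed allele labels.

    Allele labels are unique integers; autosomal loci are diploid, Y and
    mtDNA markers haploid, and the K locus a three-state dominant genotype.
    """

    name: str
    alleles: tuple[int, ...] = ()
    chromosome_class: ChromosomeClass = ChromosomeClass.AUTOSOMAL

    def __post_init__(self) -> None:
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"duplicate allele labels at locus {self.name}")


@dataclass
class IndividualMeta:
    id: str
    group: str
    sex: Sex = Sex.UNKNOWN
    phenotype_flags: frozenset[str] = frozenset()
    mtdna_hap: str | None = None
    y_hap: str | None = None
    k_genotype: KGenotype | None = None
    popflag: bool = False

    def __post_init__(self) -> None:
        if self.y_hap is not None and self.sex == Sex.F:
            raise ValueError(f"individual {self.id}: Y haplotype recorded for a female")


class GenotypeMatrix:
    """Diploid multilocus genotypes for N individuals at L autosomal loci.

    ``calls`` is an ``(N, L, 2)`` integer array of allele labels with
    :data:`MISSING` marking absent copies. The two copies of a genotype are
    unordered; callers must not attach meaning to their order.
    """

    def __init__(self, individuals: list[IndividualMeta], loci: list[Locus],
                 calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(individuals), len(loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(individuals)} individuals x {len(loci)} loci x 2"
            )
        ids = [ind.id for ind in individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids")
        for j, locus in enumerate(loci):
            observed = calls[:, j, :]
            observed = observed[observed != MISSING]
            extra = set(observed.tolist()) - set(locus.alleles)
            if extra:
                raise ValueError(
                    f"locus {locus.name}: called alleles {sorted(extra)} "
                    "not in the locus allele set"
                )
        self.individuals = list(individuals)
        self.loci = list(loci)
        self.calls = calls

    # -- basic accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.group, None)
        return list(seen)

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([ind.group == group for ind in self.individuals])

    def locus_index(self, name: str) -> int:
        for j, loc in enumerate(self.loci):
            if loc.name == name:
                return j
        raise KeyError(f"unknown locus {name!r}")

    def missingness(self) -> np.ndarray:
        """Per-individual fraction of missing allele copies."""
        return (self.calls == MISSING).mean(axis=(1, 2))

    def subset_loci(self, names: list[str]) -> "GenotypeMatrix":
        idx = [self.locus_index(n) for n in names]
        return GenotypeMatrix(
            [replace(ind) for ind in self.individuals],
            [self.loci[j] for j in idx],
            self.calls[:, idx, :].copy(),
        )

    def subset_individuals(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        inds = [replace(ind) for ind, m in zip(self.individuals, mask) if m]
        return GenotypeMatrix(inds, list(self.loci), self.calls[mask].copy())

    def concat(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if self.locus_names != other.locus_names:
            raise ValueError("locus panels differ")
        loci = [
            Locus(a.name, tuple(sorted(set(a.alleles) | set(b.alleles))),
                  a.chromosome_class)
            for a, b in zip(self.loci, other.loci)
        ]
        return GenotypeMatrix(
            [replace(i) for i in self.individuals + other.individuals],
            loci,
            np.concatenate([self.calls, other.calls], axis=0),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (f"GenotypeMatrix({self.n_individuals} individuals, "
                f"{self.n_loci} loci, groups={self.groups})")


@dataclass
class AlleleFrequencyTable:
    """Per-group, per-locus allele frequency vectors.

    ``freqs[group][locus_name]`` maps allele label -> frequency; a
    group x locus combination with zero non-missing gene copies is recorded
    in ``undefined`` instead of being given a zero vector.
    """

    groups: list[str]
    loci: list[Locus]
    freqs: dict[str, dict[str, dict[int, float]]]
    sample_size: dict[str, dict[str, int]]  # gene copies (2N) actually used
    undefined: set[tuple[str, str]] = field(default_factory=set)

    def vector(self, group: str, locus: str) -> dict[int, float]:
        if (group, locus) in self.undefined:
            raise ValueError(f"frequencies undefined for {group} x {locus}")
        return self.freqs[group][locus]

    def as_array(self, group: str, locus: Locus) -> np.ndarray:
        vec = self.vector(group, locus.name)
        return np.array([vec.get(a, 0.0) for a in locus.alleles])


def allele_frequencies(gm: GenotypeMatrix, groups: list[str] | None = None
                       ) -> AlleleFrequencyTable:
    """Estimate allele frequencies per group x locus from non-missing copies."""
    if groups is None:
        groups = gm.groups
    if not groups:
        raise ValueError("groups must be nonempty")
    freqs: dict[str, dict[str, dict[int, float]]] = {}
    sizes: dict[str, dict[str, int]] = {}
    undefined: set[tuple[str, str]] = set()
    for g in groups:
        mask = gm.group_mask(g)
        if not mask.any():
            raise ValueError(f"group {g!r} has no individuals")
        freqs[g] = {}
        sizes[g] = {}
        for j, locus in enumerate(gm.loci):
            copies = gm.calls[mask, j, :].ravel()
            copies = copies[copies != MISSING]
            sizes[g][locus.name] = copies.size
            if copies.size == 0:
                undefined.add((g, locus.name))
                freqs[g][locus.name] = {}
                continue
            labels, counts = np.unique(copies, return_counts=True)
            total = counts.sum()
            freqs[g][locus.name] = {
                int(a): c / total for a, c in zip(labels, counts)
            }
    return AlleleFrequencyTable(list(groups), list(gm.loci), freqs, sizes,
                                undefined)


@dataclass
class ValidationReport:
    per_locus_missingness: dict[str, float]
    monomorphic: list[tuple[str, str]]        # (group, locus)
    duplicate_genotypes: list[tuple[str, str]]  # pairs of individual ids

    @property
    def issues(self) -> list[str]:
        out = [f"monomorphic {g}:{l}" for g, l in self.monomorphic]
        out += [f"duplicate genotypes {a}={b}" for a, b in self.duplicate_genotypes]
        return out


def validate_dataset(gm: GenotypeMatrix) -> ValidationReport:
    """Report-only dataset screening: missingness, monomorphic loci within
    groups, and duplicated multilocus genotypes (complete matches only)."""
    miss = {
        loc.name: float((gm.calls[:, j, :] == MISSING).mean())
        for j, loc in enumerate(gm.loci)
    }
    mono: list[tuple[str, str]] = []
    for g in gm.groups:
        mask = gm.group_mask(g)
        for j, loc in enumerate(gm.loci):
            copies = gm.calls[mask, j, :].ravel()
            copies = copies[copies != MISSING]
            if copies.size and np.unique(copies).size == 1:
                mono.append((g, loc.name))
    dup: list[tuple[str, str]] = []
    # canonical per-locus sorted copies so (a,b) == (b,a)
    canon = np.sort(gm.calls, axis=2).reshape(gm.n_individuals, -1)
    for i in range(gm.n_individuals):
        for k in range(i + 1, gm.n_individuals):
            row_i, row_k = canon[i], canon[k]
            if (row_i == MISSING).all() or (row_k == MISSING).all():
                continue
            if np.array_equal(row_i, row_k):
                dup.append((gm.individuals[i].id, gm.individuals[k].id))
    return ValidationReport(miss, mono, dup)
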