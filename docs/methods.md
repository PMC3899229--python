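# Methods

This note records the models, numerical choices and known limitations behind
hybridkit, in the order an analysis flows through the package.

## Data model

Genotypes are diploid calls at unlinked autosomal STR loci; allele labels
are opaque integers and no repeat-unit (stepwise-mutation) arithmetic is
performed anywhere — every statistic is frequency-based. Uniparental markers
(mtDNA control-region and Y-STR haplotypes) enter as labels; sequence
alignment and haplotype calling are upstream of the package, which provides
only exact-identity collapsing. The K-locus (*CBD103* melanistic deletion)
is stored as a three-state genotype, never as an allele frequency, because
the assay distinguishes heterozygous carriers from homozygotes. Groups are
free-form strings so the toolkit generalises beyond the canonical eight
sampling groups. Missing data: a missing allele copy is excluded from
frequency estimation (never treated as a zero-frequency allele), a
group × locus cell with no data is flagged undefined, and likelihood-based
methods skip missing loci.

## Diversity and differentiation

Per-group summaries follow the conventions of standard population-genetics
toolkits: mean alleles per locus, private alleles (absent from every other
group in the dataset), observed heterozygosity, unbiased expected
heterozygosity UHe = (2N/(2N−1))(1 − Σp²), and probability-of-identity
panels PID = Π[2(Σp²)² − Σp⁴] and PIDsibs = Π[¼ + ½Σp² + ½(Σp²)² − ¼Σp⁴].

Hardy–Weinberg departure is summarised by multilocus F_IS = 1 − Ho/UHe
(loci weighted by genotyped sample size) with a permutation p-value built by
shuffling allele copies among individuals within each locus. Genotypic
linkage disequilibrium uses a G statistic on the two-locus genotype table
with one locus permuted across individuals; significance is
Bonferroni-corrected over the locus-pair family within each group. The
permutation route was chosen over asymptotic chi-square because
microsatellite genotype tables are sparse; the G statistic itself is a
declared choice (the classical software does not document its statistic) and
is validated only against its own permutation null. Defaults: 1000
permutations, explicit seed required in the CLI.

Differentiation uses the 1984 variance-components estimator θ with the
published unequal-sample-size weighting; multilocus and panel-level values
pool components across loci and alleles (ratio of sums, never a mean of
ratios), and loci monomorphic across the contributing groups are excluded.
The distance-based analogue Φ_PT runs a one-level AMOVA on squared
distances — squared Euclidean on per-individual allele-count vectors for STR
genotypes, 0/1 mismatch for haplotypes — with label-permutation p-values.
Note that Φ_PT between a monomorphic group and a diverse one is bounded well
below 1 by the diverse group's internal variance even when the groups share
no haplotype (the packaged mtDNA table gives Φ_PT = 0.7067 for the
wolf-vs-village-dog contrast, derived exactly from the count table).

Queller–Goodnight relatedness is the symmetric estimator: numerators and
denominators summed over loci before the ratio, both individuals serving as
focal. The accompanying Welch t-test on sets of pairwise r values carries a
documented caveat: pairs sharing individuals are not independent, so the
p-value is indicative.

## Synthetic parental populations

The generator emulates two diverged gene pools with the survey's summary
statistics as its defaults: 39 loci, 12 alleles per locus ancestrally,
wolf-side Ho 0.46, dog-side Ho 0.71, multilocus θ 0.25, 60 diploids per
pool. Construction: ancestral frequencies per locus from a symmetric
Dirichlet(1) (expected ancestral heterozygosity ≈ 0.85, needed so the
dog-side target is attainable); both populations drift by a common
Balding–Nichols parameter F (frequencies ~ Dirichlet(p_anc(1−F)/F)); each
population's allele richness is then thinned — repeatedly deleting the
rarest allele of a stochastically chosen high-heterozygosity locus — until
its mean expected heterozygosity reaches the target. F is found by bisection
on the realized multilocus θ of a full genotype draw and a draw is accepted
only within the stated tolerance (0.03), so the returned dataset always
satisfies the calibration; Ho is verified within 0.05 (warning otherwise).
Thinning matters scientifically: it creates hard allele absences, the
private alleles that make real parental populations crisply assignable. The
generator reproduces the qualitative asymmetry of the real system (the less
diverse pool retains ~2 alleles/locus, the diverse pool ~5–6 with >100
private alleles).

What the generator does **not** emulate: genotyping error, null alleles and
allelic dropout; linkage between loci; within-population structure or
relatedness; and — importantly for threshold calibration — the phenotypic
pre-screening of real reference samples. Simulated parentals are plain
Hardy–Weinberg draws, so a small fraction are genuinely intermediate-looking
("unscreened"), giving the parental self-ancestry distribution a fatter left
tail than a curated empirical reference panel. Passing power tests therefore
demonstrate correct behaviour of the machinery under honest synthetic
conditions, not the exact operating numbers of any particular empirical
survey (see Power analysis below).

Hybrid classes are composed by pedigree — F1 = W×D, F2 = F1×F1,
BC1W = F1×W, BC2W = BC1W×W, BC3W = BC2W×W, mirrored on the dog side — with
every offspring allele an independent draw from a parental pool's
allele-frequency distribution (the behaviour of the standard hybrid
simulator; family structure within pools is deliberately ignored).
Intermediate pools keep the per-class size (default 60). An alternative
reading of third-generation backcrosses as F2×parental is exposed via
`alt_bc3=True`; the successive-backcross reading is the default. Expected
wolf-genome fractions per class are the pedigree values (F1/F2 0.5,
BC1W 0.75, BC2W 0.875, BC3W 0.9375, dog-side mirrored).

## Admixture inference

The Gibbs sampler follows the classic admixture model with independent
cluster frequencies: copy origins z, cluster frequencies P ~ Dirichlet(λ),
ancestries q_i ~ Dirichlet(α). λ = 1 fixed; α is initialised at 1.0 with a
uniform prior on (0, 10] and a Metropolis random-walk step of sd 0.025 (the
defaults of the classical implementation). With prior population information
(`use_popinfo`), flagged reference individuals have q pinned to their
declared cluster, and `update_freqs_from_flagged_only` restricts frequency
learning to them — a deliberate simplification that omits the classical
tool's migration-rate elaboration. Label switching is handled after the
fact: chains beyond the first are aligned to the first by greedy bijective
matching on mean ancestry columns; under popinfo the clusters are identified
by construction. Ties in alignment resolve by flagged-membership mass, then
first-individual index.

Model evidence per K is mean(lnL) − var(lnL)/2 over retained sweeps
(constant terms dropped — differences across K are what matters), and ΔK is
the absolute second difference of mean lnP(D) across consecutive K divided
by the across-chain standard deviation. 90% credible intervals are empirical
quantiles of thinned, pooled ancestry samples.

Run lengths: library defaults are a tenth of classical practice (40 000
post-burn-in sweeps + 4 000 burn-in, 2 chains); the power study and tests
use shorter, explicitly configured runs (typically 2 000 + 1 000, one chain)
— with K = 2 and strong structure the chain equilibrates within a few
hundred sweeps, and the α random walk needs roughly a thousand sweeps to
equilibrate, which sets the burn-in floor. A key behaviour worth knowing:
α adapts to the panel's composition. A panel dominated by parentals drives
α toward ~0.05 and pushes everyone to the simplex corners; a panel rich in
admixed classes holds α near 0.3–0.5. Power analyses therefore analyse the
reference parentals together with all simulated classes in one run, matching
how such studies are actually conducted.

## Assignment and class inference

The leave-one-out assignment score uses the posterior-predictive genotype
probability under a Dirichlet(1/k_ℓ) prior on each group's allele counts
(k_ℓ = alleles at the locus), removing the individual's own copies when
scoring its own group; the prior guarantees nonzero mass for alleles unseen
in a group. Percent scores are normalised likelihoods × 100.

The six-class genotype-class sampler fixes the genotype-origin weights
φ_c = P((W,W), (W,D), (D,D)) per class — parentals (1,0,0)/(0,0,1),
F1 (0,1,0), F2 (¼,½,¼), backcrosses (½,½,0)/(0,½,½) — and Gibbs-samples
class labels, mixing proportions (Dirichlet(1)), copy origins and the two
source frequency vectors. The "uniform" frequency prior is Dirichlet(1) per
allele and the "Jeffreys-like" prior Dirichlet(0.5) (the constant is
configurable since the original tool's exact value is undocumented).
Across-chain agreement is monitored by a Gelman–Rubin statistic on the
log-likelihood trace (warning above 1.2). Classes beyond the first
backcross are not in the model; deeper backcrosses land on BC or parental,
which is the model's designed behaviour, and class recovery degrades
BC1 → BC2 → BC3.

The non-Bayesian reallocation clusterer runs 50 random starts × 20
reallocation sweeps (LOD threshold 0 = always move to the best group),
reseeding emptied groups with the worst-fitting individual, and reports
run-to-run agreement of the modal partition (canonical labelling) — a
simplified plateau report in place of the original tool's full stopping
heuristics, which the survey used only for coarse partitioning.

The empirical-null admixture test simulates non-admixed genotypes from each
reference group's frequencies, runs one reference-anchored admixture
analysis (popinfo with frequencies from flagged individuals only, for
stability and speed), and takes the (1−α) order statistic of the simulated
parentals' non-self ancestry as the significance threshold (rank
⌈(1−α)·n⌉ of the sorted null; #95 of 100 at α = 0.05). An observed
individual is significantly admixed iff its non-self ancestry strictly
exceeds its nearest cluster's threshold. On held-out parental test sets the
false-positive rate is calibrated near α.

## Panel selection and power analysis

Loci are ranked by per-locus θ between the two reference groups (ties by
allele-frequency differential δ = ½Σ|p_A − p_B|, then name); a greedy
forward selection by leave-one-out self-assignment accuracy provides the
confirmatory ranking, and a consistency report flags loci whose ranks
disagree by more than a quarter of the panel (the reconciliation rule is
ours; the original survey does not state one). Panels are prefixes of the
ranking plus named legacy panels kept verbatim (historical monitoring
panels are not divergence-ranked, so they are never treated as prefixes).

Thresholds on self-ancestry are calibrated on simulated parentals: the
default min-parental rule takes the minimum observed self-ancestry (so no
calibration parental is ever called admixed); a γ-quantile rule (default
γ = 0.01) is provided for robustness to single outliers. Detection of a
simulated hybrid means its largest parental-cluster ancestry falls below
the threshold; a credible-interval variant counts an individual detected
when the upper 90% credible bound of parental ancestry stays below a
cutoff (default 0.995, the numerical rendering of "the interval excludes
1" — posterior draws never reach 1 exactly). Per-class proportions carry
Clopper–Pearson 95% intervals.

Two systematic behaviours deserve emphasis. First, the min-parental
threshold is an extreme order statistic: with 120 simulated parentals its
replicate-to-replicate spread is large (roughly 0.90–0.97 under the default
conditions), and because the BC2 ancestry distribution sits at ~0.91 ± 0.06,
the BC2-vs-parental confusion it implies swings widely (from ~10% to ~70%
across replicates; five-replicate averages land near 35–50%). An empirical
survey with pre-screened reference animals sits at the tight end of that
range. Second, panel-size effects must be read against panel content:
shrinking a panel by dropping loci at random lowers parental self-ancestry,
lowers thresholds and widens credible intervals monotonically, but a
divergence-ranked subset (the top-24) can outperform the full panel — that
concentration of information is precisely the argument for marker
selection.

## Consensus classification

Evidence per individual is reduced to flags: multilocus admixture at the
39- and 24-locus panels (no-prior runs, thresholds 0.985/0.980), a 12-locus
flag that fires if either run mode (with or without prior population
information) falls below 0.960, an assignment-score flag (percent ≥ 90 on
the 39- or 24-locus panel; the cutoff separates the evidence table's high
scores from its low ones and is configurable), a reallocation hybrid call,
empirical-null significance, and the six-class posterior. The default rule
set scores these six signals, adds one for a dog-derived uniparental marker,
and decides: F1/F2 posterior with ≥ 4 signals keeps its class; ≥ 2 signals
means backcross; ≤ 1 signal with melanism, anomalous phenotype or a variant
(non-local or private) haplotype means introgressed; a 12-locus-only signal
is a presumptive false positive; anything else is parental. Every fired rule
is recorded in a trace, and contradictions (e.g. a recent-hybrid posterior
with no support) are logged rather than silently resolved. Marker-state
dictionaries (which haplotypes are local-wolf, dog-derived, private, …) are
editable CSV data, not code. On the packaged 30-sample evidence table the
default rule set reproduces 27 of 30 recorded final identifications; the
three exceptions are rows whose recorded calls are mutually inconsistent
under any single threshold rule we could state, and the package never
overrides the recorded column — tallies always read it directly.

## Reproducibility

Every stochastic routine takes an explicit seed and derives child seeds from
a single generator, so identical inputs give bit-identical outputs; derived
seeds stay below 2³¹. The pipeline writes a manifest with versions, seeds
and SHA-256 hashes of all outputs. Packaged fixtures are integrity-checked
against recorded digests at load time. Problem sizes used by the bundled
study runner — 39 loci, 60 + 60 parentals, 60 genotypes per class, 2 000
post-burn-in sweeps, five replicates — are the package's chosen desk-scale
defaults for the study design it implements.
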