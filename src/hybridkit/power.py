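"""Threshold calibration and detection-power analysis across marker panels.

The detection rule mirrors standard practice in hybrid surveys: an
individual counts as admixed when its largest parental-cluster ancestry q
falls below a threshold calibrated on simulated non-admixed parentals.
Shrinking the panel lowers parental self-ancestry (background noise grows),
so calibrated thresholds decrease with panel size and credible intervals
widen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .admixture import AdmixtureConfig, AdmixtureResult, run_admixture_mcmc
from .classify import admixture_null_test
from .core import GenotypeMatrix
from .simulate import HybridClass, SimPanel, expected_ancestry


@dataclass
class ThresholdCalibration:
    panel: str
    threshold: float
    rule: str
    n_parentals: int
    seed: int | None = None


def calibrate_threshold(parental_q: np.ndarray, rule: str = "min_parental",
                        panel: str = "full", gamma: float = 0.01,
                        seed: int | None = None) -> ThresholdCalibration:
    """Ancestry threshold from simulated parental self-ancestry values.

    ``min_parental`` uses the minimum observed value (every simulated
    parental stays above threshold by construction); ``quantile`` uses the
    gamma-quantile for robustness to a stray simulated outlier.
    """
    q = np.asarray(parental_q, dtype=float)
    if q.size < 50:
        warnings.warn("fewer than 50 simulated parentals: threshold is noisy")
    if rule == "min_parental":
        t = float(q.min())
    elif rule == "quantile":
        if gamma >= 0.5:
            raise ValueError("quantile rule needs gamma < 0.5")
        t = float(np.quantile(q, gamma))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return ThresholdCalibration(panel, t, rule, int(q.size), seed)


def parental_ancestry(result: AdmixtureResult, parental_clusters: list[str]
                      ) -> pd.Series:
    """Largest parental-cluster ancestry per individual (the quantity
    thresholded for admixture detection)."""
    return result.q[parental_clusters].max(axis=1)


def evaluate_power(sim: SimPanel, result: AdmixtureResult,
                   calib: ThresholdCalibration,
                   parental_clusters: list[str],
                   ci_cutoff: float = 0.995) -> pd.DataFrame:
    """Per-class detection table at the calibrated threshold.

    detection: q (max parental ancestry) below threshold. The CI criterion
    counts an individual detected when the upper 90% credible bound of its
    parental ancestry stays below ``ci_cutoff`` (numerical stand-in for "the
    credible interval excludes 1"). Clopper-Pearson 95% intervals accompany
    each proportion.
    """
    qp = parental_ancestry(result, parental_clusters)
    ci_up = result.ci_upper[parental_clusters].max(axis=1)
    rows = []
    groups = [ind.group for ind in sim.matrix.individuals]
    for cls in sim.classes:
        ids = [ind.id for ind, g in zip(sim.matrix.individuals, groups)
               if g == cls.value]
        if not ids:
            continue
        q = qp.loc[ids]
        detected = int((q < calib.threshold).sum())
        ci_detected = int((ci_up.loc[ids] < ci_cutoff).sum())
        n = len(ids)
        lo, hi = _clopper_pearson(detected, n)
        rows.append({
            "class": cls.value,
            "expected_w_ancestry": expected_ancestry(cls),
            "n": n,
            "detected": detected,
            "prop_detected": detected / n,
            "ci95_low": lo,
            "ci95_high": hi,
            "ci_detected": ci_detected,
            "prop_ci_detected": ci_detected / n,
            "mean_parental_q": float(q.mean()),
        })
    return pd.DataFrame(rows).set_index("class")


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    a = (1 - level) / 2
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - a, k + 1, n - k))
    return lo, hi


def false_positive_sweep(gm: GenotypeMatrix, reference_groups: list[str],
                         panels: dict[str, list[str]], n_sim: int = 100,
                         n_test: int = 60, alpha: float = 0.05, seed: int = 0,
                         mcmc: AdmixtureConfig | None = None) -> pd.DataFrame:
    """False-positive rate of the empirical-null admixture test per panel.

    For each panel, held-out parental genotypes are simulated from each
    reference group and screened with :func:`admixture_null_test`; the FP
    rate is the fraction flagged significant, reported with a binomial CI.
    """
    from .classify import simulate_parental_genotypes

    rng = np.random.default_rng(seed)
    rows = []
    for name, loci in panels.items():
        sub = gm.subset_loci(loci)
        if len(loci) == 1:
            warnings.warn(f"panel {name}: single locus, FP estimate is degenerate")
        test = None
        for g in reference_groups:
            sims = simulate_parental_genotypes(
                sub, g, n_test, int(rng.integers(0, 2 ** 31 - 1)),
                id_prefix=f"test{g}")
            for ind in sims.individuals:
                ind.group = f"test_{g}"
            test = sims if test is None else test.concat(sims)
        combined = sub.concat(test)
        calib = admixture_null_test(
            combined, reference_groups, n_sim=n_sim, alpha=alpha,
            seed=int(rng.integers(0, 2 ** 31 - 1)), mcmc=mcmc)
        flags = calib.significant
        flags = flags[flags["group"].str.startswith("test_")]
        k, n = int(flags["significant"].sum()), len(flags)
        lo, hi = _clopper_pearson(k, n)
        rows.append({"panel": name, "n_loci": len(loci), "n_test": n,
                     "false_positives": k, "fp_rate": k / n,
                     "ci95_low": lo, "ci95_high": hi, "alpha": alpha,
                     "seed": seed})
    return pd.DataFrame(rows).set_index("panel")


def panel_comparison_report(power_tables: dict[str, pd.DataFrame],
                            thresholds: dict[str, ThresholdCalibration],
                            panel_theta: dict[str, float],
                            fp_rates: dict[str, float] | None = None,
                            ci_width: dict[str, float] | None = None
                            ) -> pd.DataFrame:
    """One row per panel: divergence, calibrated threshold, per-class power,
    FP rate and mean parental CI width; flags the smallest panel whose
    F1 + BC1 power is within 2% of the best."""
    rows = []
    for name, table in power_tables.items():
        row: dict = {
            "panel": name,
            "theta": panel_theta.get(name),
            "threshold": thresholds[name].threshold,
        }
        for cls in table.index:
            row[f"power_{cls}"] = table.loc[cls, "prop_detected"]
        if fp_rates:
            row["fp_rate"] = fp_rates.get(name)
        if ci_width:
            row["mean_parental_ci_width"] = ci_width.get(name)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("panel")
    key_cols = [c for c in df.columns
                if c in ("power_F1", "power_BC1W", "power_BC1D")]
    if key_cols:
        combined = df[key_cols].mean(axis=1)
        eligible = df.index[combined >= combined.max() - 0.02]
        df["recommended"] = False
        if len(eligible):
            # callers pass panels in descending size order, so the last
            # eligible entry is the smallest panel within 2% of the best
            df.loc[eligible[-1], "recommended"] = True
    return df


def bc2_misassignment_study(seed: int, n_seeds: int = 5,
                            n_per_class: int = 60,
                            mcmc: AdmixtureConfig | None = None,
                            log=None) -> pd.DataFrame:
    """Replicate the simulated-backcross power analysis.

    For each replicate: two calibrated parental populations (39 loci,
    theta ~ 0.25, Ho 0.46 / 0.71, 60 + 60) are pooled with eight simulated
    hybrid classes (60 genotypes each) into one two-cluster admixture run
    with no prior population information; the detection threshold is the
    minimum self-ancestry among the parental individuals, and each class's
    misassignment is the fraction of its individuals at or above that
    threshold. Returns one row per replicate with the threshold and
    per-class confusion percentages.
    """
    from .simulate import HybridClass, SyntheticPopSpec, simulate_class_panel, \
        simulate_parental_pops

    classes = [HybridClass.F1, HybridClass.F2, HybridClass.BC1W,
               HybridClass.BC1D, HybridClass.BC2W, HybridClass.BC2D,
               HybridClass.BC3W, HybridClass.BC3D]
    master = np.random.default_rng(seed)
    rows = []
    for rep in range(n_seeds):
        rng = np.random.default_rng(int(master.integers(0, 2 ** 31 - 1)))
        pops = simulate_parental_pops(
            SyntheticPopSpec(seed=int(rng.integers(0, 2 ** 31 - 1))))
        w = pops.subset_individuals(pops.group_mask("W"))
        d = pops.subset_individuals(~pops.group_mask("W"))
        sim = simulate_class_panel(w, d, classes, n_per_class,
                                   seed=int(rng.integers(0, 2 ** 31 - 1)))
        panel = pops.concat(sim.matrix)
        cfg = mcmc or AdmixtureConfig(K=2, n_burnin=1_000, n_iter=2_000,
                                      n_chains=1, thin=10)
        cfg = AdmixtureConfig(**{**cfg.__dict__,
                                 "seed": int(rng.integers(0, 2 ** 31 - 1))})
        result = run_admixture_mcmc(panel, cfg)
        groups = pd.Series([ind.group for ind in panel.individuals],
                           index=result.q.index)
        q_self = result.q.max(axis=1)
        parental = q_self[groups.isin(["W", "D"])]
        calib = calibrate_threshold(parental.to_numpy(), rule="min_parental",
                                    panel="full", seed=seed)
        row = {"replicate": rep, "threshold": calib.threshold,
               "parental_mean_q": float(parental.mean())}
        for cls in classes:
            conf = float((q_self[groups == cls.value] >= calib.threshold).mean())
            row[f"confused_{cls.value}"] = 100.0 * conf
        bc2 = q_self[groups.isin(["BC2W", "BC2D"])]
        row["confused_BC2"] = 100.0 * float((bc2 >= calib.threshold).mean())
        rows.append(row)
        if log:
            log(f"replicate {rep}: threshold {calib.threshold:.3f}, "
                f"BC2 misassigned {row['confused_BC2']:.1f}%")
    return pd.DataFrame(rows).set_index("replicate")


def check_threshold_monotonicity(calibs: dict[int, ThresholdCalibration]
                                 ) -> bool:
    """True when thresholds are non-increasing as panel size decreases
    (keys = panel sizes); emits a warning otherwise."""
    sizes = sorted(calibs, reverse=True)
    ts = [calibs[s].threshold for s in sizes]
    ok = all(a >= b - 1e-12 for a, b in zip(ts, ts[1:]))
    if not ok:
        warnings.warn("calibrated thresholds are not monotone in panel size")
    return ok
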