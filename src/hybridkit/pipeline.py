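"""End-to-end orchestration: simulate -> select panels -> admixture ->
calibrate thresholds -> power and false-positive tables -> consensus tally.

``run_pipeline`` is the importable entry point; the CLI ``hybridkit run``
wraps it. The bundled "survey mode" reproduces the full simulation study
at desk scale: two calibrated parental populations, hybrid-class panels,
admixture inference on nested marker panels, threshold calibration and the
consensus tally over the packaged evidence table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admixture import AdmixtureConfig, run_admixture_mcmc
from .consensus import consensus_tally, load_fixture_tables
from .core import GenotypeMatrix
from .panels import build_panels, rank_by_fst
from .power import (ThresholdCalibration, calibrate_threshold, evaluate_power,
                    false_positive_sweep, panel_comparison_report,
                    parental_ancestry)
from .simulate import (HybridClass, SimPanel, SyntheticPopSpec,
                       simulate_class_panel, simulate_parental_pops)


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "hybridkit_run"
    n_loci: int = 39
    target_fst: float = 0.25
    target_ho: dict = field(default_factory=lambda: {"W": 0.46, "D": 0.71})
    n_parents: int = 60
    n_per_class: int = 60
    panel_sizes: list = field(default_factory=lambda: [24, 12])
    classes: list = field(default_factory=lambda: [
        "P_W", "P_D", "F1", "F2", "BC1W", "BC1D", "BC2W", "BC2D"])
    mcmc_iter: int = 2_000
    mcmc_burnin: int = 500
    mcmc_chains: int = 1
    fp_n_sim: int = 100
    fp_n_test: int = 40
    alpha: float = 0.05

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _admixture_on_panel(panel_gm: GenotypeMatrix, cfg: RunConfig, seed: int):
    mcmc = AdmixtureConfig(K=2, n_burnin=cfg.mcmc_burnin, n_iter=cfg.mcmc_iter,
                           n_chains=cfg.mcmc_chains, seed=seed, thin=5)
    return run_admixture_mcmc(panel_gm, mcmc)


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Execute the full simulation-study pipeline and write per-stage
    reports plus a manifest (versions, seeds, output hashes) to
    ``config.out_dir``. Returns the report bundle as a dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    bundle: dict = {}
    t0 = time.time()

    def stage(name: str):
        log(f"[{time.time() - t0:7.1f}s] {name}")

    try:
        stage("simulate parental populations")
        spec = SyntheticPopSpec(
            n_loci=config.n_loci, target_fst=config.target_fst,
            target_ho=dict(config.target_ho),
            n_individuals={k: config.n_parents for k in config.target_ho},
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        parents = simulate_parental_pops(spec)

        stage("rank loci and build panels")
        ranking = rank_by_fst(parents, "W", "D")
        legacy = {"legacy12": sorted(
            rng.choice(parents.locus_names, size=min(12, config.n_loci),
                       replace=False).tolist())}
        panels = build_panels(parents, ranking, list(config.panel_sizes),
                              "W", "D", legacy=legacy)
        pd.DataFrame([dataclasses.asdict(s) for s in ranking]).to_csv(
            out / "locus_ranking.csv", index=False)
        bundle["panel_theta"] = panels.panel_theta

        stage("simulate hybrid classes")
        w_mask = parents.group_mask("W")
        sim = simulate_class_panel(
            parents.subset_individuals(w_mask),
            parents.subset_individuals(~w_mask),
            [HybridClass(c) for c in config.classes],
            n_per_class=config.n_per_class,
            seed=int(rng.integers(0, 2 ** 31 - 1)))

        power_tables, thresholds, ci_widths = {}, {}, {}
        panel_defs = {"full": parents.locus_names,
                      **{f"top{s}": panels.panels[f"top{s}"]
                         for s in sorted(set(config.panel_sizes), reverse=True)},
                      "legacy12": panels.panels["legacy12"]}
        for name, loci in panel_defs.items():
            stage(f"admixture + power on panel {name} ({len(loci)} loci)")
            panel_gm = sim.matrix.subset_loci(loci)
            result = _admixture_on_panel(panel_gm, config,
                                         int(rng.integers(0, 2 ** 31 - 1)))
            # identify the parental clusters from the simulated parental classes
            clusters = list(result.q.columns)
            qp = parental_ancestry(result, clusters)
            par_ids = [ind.id for ind in sim.matrix.individuals
                       if ind.group in ("P_W", "P_D")]
            calib = calibrate_threshold(qp.loc[par_ids].to_numpy(),
                                        panel=name, seed=config.seed)
            thresholds[name] = calib
            table = evaluate_power(sim, result, calib, clusters)
            table.to_csv(out / f"power_{name}.csv")
            power_tables[name] = table
            width = (result.ci_upper.loc[par_ids, clusters].max(axis=1)
                     - result.ci_lower.loc[par_ids, clusters].max(axis=1))
            ci_widths[name] = float(width.mean())

        stage("false-positive sweep")
        fp = false_positive_sweep(
            parents, ["W", "D"], panel_defs, n_sim=config.fp_n_sim,
            n_test=config.fp_n_test, alpha=config.alpha,
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        fp.to_csv(out / "false_positive_rates.csv")

        stage("panel comparison report")
        report = panel_comparison_report(
            power_tables, thresholds, panels.panel_theta,
            fp_rates=fp["fp_rate"].to_dict(), ci_width=ci_widths)
        report.to_csv(out / "panel_comparison.csv")
        bundle["panel_comparison"] = report

        stage("consensus tally over the packaged evidence table")
        table4 = load_fixture_tables("table4")
        tally = consensus_tally(table4["final_id"])
        (out / "consensus_tally.json").write_text(json.dumps(tally, indent=2))
        bundle["consensus_tally"] = tally
        bundle["thresholds"] = {k: v.threshold for k, v in thresholds.items()}
        bundle["fp_rates"] = fp["fp_rate"].to_dict()
    except Exception as exc:  # partial outputs stay on disk for inspection
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest = {
        "hybridkit_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "elapsed_s": round(time.time() - t0, 1),
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    stage("done")
    return bundle
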