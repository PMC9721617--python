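"""End-to-end orchestration: simulate -> fit -> compare -> report.

Every stochastic stage receives its own seed derived from one master seed
through a fixed ``numpy.random.SeedSequence`` fan-out (stage index = spawn
key), so a pipeline run is fully reproducible from its config alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import evaluate, io, stayglm
from .cohort import CohortSpec
from .exceptions import ConfigError
from .hbayes import CohortData, fit_hierarchical

log = logging.getLogger("twostep")

STAGE_SEEDS = {"simulate": 0, "fit": 1, "glm": 2, "compare": 3, "ppc": 4}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    outdir: str
    cohort_csv: str | None = None
    spec: CohortSpec | None = None
    models: tuple[str, ...] = ("M1",)
    chains: int = 4
    iterations: int = 3000
    warmup: int = 1000
    master_seed: int = 0
    serum: bool = False
    glm_random_effects: str = "full"
    run_glm: bool = True
    run_ppc: bool = True
    fast: bool = False

    def __post_init__(self):
        if self.cohort_csv is None and self.spec is None:
            raise ConfigError("pipeline needs either cohort_csv or a synthetic spec")
        if self.fast:
            self.chains = max(2, self.chains // 2)
            self.iterations = max(400, self.iterations // 3)
            self.warmup = max(200, self.warmup // 3)

    def stage_seed(self, stage: str) -> int:
        child = np.random.SeedSequence(
            (self.master_seed, STAGE_SEEDS[stage]))
        return int(child.generate_state(1)[0] % 2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a manifest of written files."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    t_start = time.time()

    def stage(name):
        log.info("stage %s (seed %d)", name,
                 config.stage_seed(name) if name in STAGE_SEEDS else -1)

    if config.spec is not None:
        stage("simulate")
        from .cohort import generate_cohort
        trials, truth = generate_cohort(config.spec)
        io.write_trials(trials, out / "trials.csv")
        truth.to_csv(out / "ground_truth.csv", index=False)
        manifest["trials"] = str(out / "trials.csv")
        manifest["ground_truth"] = str(out / "ground_truth.csv")
    else:
        trials = io.read_trials(config.cohort_csv)

    stage("fit")
    fits = {}
    logliks = {}
    for j, model in enumerate(config.models):
        fit = fit_hierarchical(
            trials, model, chains=config.chains, iterations=config.iterations,
            warmup=config.warmup, seed=config.stage_seed("fit") + j,
            serum_covariate=config.serum)
        fits[model] = fit
        summ = fit.summary()
        summ.to_csv(out / f"coefficients_{model}.csv", index=False)
        manifest[f"coefficients_{model}"] = str(out / f"coefficients_{model}.csv")
        rh = fit.rhat()
        rh.to_csv(out / f"rhat_{model}.csv")
        manifest[f"rhat_{model}"] = str(out / f"rhat_{model}.csv")
        if fit.warnings:
            log.warning("model %s: %s", model, "; ".join(fit.warnings))
        data = CohortData(trials, model, config.serum)
        logliks[model] = evaluate.pointwise_loglik(fit, data)
        fit.to_netcdf(out / f"draws_{model}.nc")
        manifest[f"draws_{model}"] = str(out / f"draws_{model}.nc")

    if len(config.models) > 1:
        stage("compare")
        cmp_res = evaluate.loo_compare(
            logliks, seed=config.stage_seed("compare"))
        cmp_res.table.to_csv(out / "model_comparison.csv")
        cmp_res.pairwise.to_csv(out / "model_comparison_pairwise.csv", index=False)
        manifest["model_comparison"] = str(out / "model_comparison.csv")
        best = cmp_res.best
    else:
        best = config.models[0]

    if config.run_glm:
        stage("glm")
        table = stayglm.build_stay_table(trials)
        glm = stayglm.fit_stay_glm(
            table, chains=config.chains, iterations=config.iterations,
            warmup=config.warmup, seed=config.stage_seed("glm"),
            serum=config.serum, random_effects=config.glm_random_effects)
        glm.summary().to_csv(out / "stay_glm_coefficients.csv", index=False)
        manifest["stay_glm_coefficients"] = str(out / "stay_glm_coefficients.csv")
        if glm.warnings:
            log.warning("stay glm: %s", "; ".join(glm.warnings))

    if config.run_ppc:
        stage("ppc")
        ppc = evaluate.posterior_predictive_check(
            fits[best], trials, seed=config.stage_seed("ppc"))
        ppc.stay_curves.to_csv(out / "ppc_stay_curves.csv", index=False)
        evaluate.plot_stay_curves(ppc, out / "ppc_stay_curves.png")
        manifest["ppc_stay_curves"] = str(out / "ppc_stay_curves.csv")

    manifest["runtime_seconds"] = f"{time.time() - t_start:.1f}"
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": {k: str(v) for k, v in vars(config).items()},
                   "outputs": manifest}, fh, indent=2)
    return manifest
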