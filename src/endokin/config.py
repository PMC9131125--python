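"""Run configuration and the staged analysis pipeline.

A single flat YAML config drives every stage; artifacts land in a run
directory together with a manifest recording the config hash, seeds and
per-stage diagnostics, so any run can be reproduced exactly.  Stages:

    simulate          synthetic dataset + ground truth
    fit-gmfi          homogeneous-model MLE from GMFI series
    calibrate-weights discrepancy weight calibration
    abc-smc           SMC pilot: threshold epsilon + global minimum
    abc-mcmc          tuned ABC-MCMC chains
    best-fit          lowest-average-discrepancy point estimate
    predict           posterior predictions of unobservable quantities

Later stages read the artifacts of earlier ones from the run directory, so
the pipeline can be resumed or run stage-by-stage from the command line.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abc as abc_mod
from . import predict as predict_mod
from .abc import ABCProblem, DiscrepancyConfig, PosteriorChain, default_prior_box
from .gmfi_fit import GmfiSeries, fit_homogeneous
from .measurement import Dataset, MeasurementParams, estimate_quench_efficiency
from .population import PopulationParams
from .synthetic_data import (
    AutofluorescenceModel,
    StudyDesign,
    default_measurement,
    default_population,
    generate_dataset,
    load_dataset,
    write_dataset,
)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("endokin")

STAGES = (
    "simulate",
    "fit-gmfi",
    "calibrate-weights",
    "abc-smc",
    "abc-mcmc",
    "best-fit",
    "predict",
)

_STAGE_DEPS = {
    "simulate": (),
    "fit-gmfi": ("simulate",),
    "calibrate-weights": ("simulate",),
    "abc-smc": ("simulate",),
    "abc-mcmc": ("simulate", "abc-smc"),
    "best-fit": ("simulate", "abc-mcmc"),
    "predict": ("simulate", "best-fit"),
}

_STAGE_ARTIFACTS = {
    "simulate": "dataset/manifest.yaml",
    "fit-gmfi": "gmfi_fit.csv",
    "calibrate-weights": "weights.yaml",
    "abc-smc": "smc.yaml",
    "abc-mcmc": "chain.csv",
    "best-fit": "best_fit.yaml",
    "predict": "predict_manifest.yaml",
}


@dataclass
class RunConfig:
    """Flat run configuration with per-stage sections.

    ``raw`` holds the config mapping as loaded; convenience accessors build
    the typed parameter objects with defaults filled in.  ``seed`` feeds a
    SeedSequence from which every stage derives an independent stream.
    """

    outdir: Path
    seed: int = 0
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, outdir=None, seed=None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            outdir=Path(outdir if outdir is not None else raw.get("outdir", "run")),
            seed=int(seed if seed is not None else raw.get("seed", 0)),
            raw=raw,
        )

    def section(self, name: str) -> dict:
        return dict(self.raw.get(name, {}) or {})

    def config_hash(self) -> str:
        payload = json.dumps({"raw": self.raw, "seed": self.seed}, sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # -- typed accessors -----------------------------------------------------

    def population(self) -> PopulationParams:
        base = default_population().to_dict()
        base.update(self.section("simulate").get("population", {}) or {})
        return PopulationParams.from_dict(base)

    def measurement(self) -> MeasurementParams:
        mp = default_measurement()
        over = self.section("simulate").get("measurement", {}) or {}
        return replace(mp, **over)

    def design(self, seed: int) -> StudyDesign:
        d = self.section("simulate").get("design", {}) or {}
        return StudyDesign(
            times=tuple(d.get("times", StudyDesign().times)),
            n_per_sample=int(d.get("n_per_sample", 1000)),
            n_autofluorescence=int(d.get("n_autofluorescence", 5000)),
            seed=seed,
        )

    def af_model(self) -> AutofluorescenceModel:
        d = self.section("simulate").get("autofluorescence", {}) or {}
        return AutofluorescenceModel(**d)

    def discrepancy(self) -> DiscrepancyConfig:
        return DiscrepancyConfig(**self.section("discrepancy"))


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    """Stable per-stage substream seed below 2**31."""
    h = hashlib.sha256(f"{cfg.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _require(cfg: RunConfig, stage: str) -> None:
    for dep in _STAGE_DEPS[stage]:
        if not (cfg.outdir / _STAGE_ARTIFACTS[dep]).exists():
            raise FileNotFoundError(
                f"stage '{stage}' requires artifacts of stage '{dep}' "
                f"(missing {_STAGE_ARTIFACTS[dep]} in {cfg.outdir})"
            )


def _append_manifest(cfg: RunConfig, stage: str, info: dict) -> None:
    path = cfg.outdir / "run_manifest.yaml"
    manifest = {}
    if path.exists():
        with open(path) as fh:
            manifest = yaml.safe_load(fh) or {}
    manifest[stage] = {
        "config_hash": cfg.config_hash(),
        "seed": _stage_seed(cfg, stage),
        **info,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh)


def _load_run_dataset(cfg: RunConfig) -> Dataset:
    return load_dataset(cfg.outdir / "dataset")


def _build_problem(cfg: RunConfig, ds: Dataset) -> ABCProblem:
    sec = cfg.section("abc")
    gs = GmfiSeries.from_dataset(ds)
    gmax = float(max(gs.unquenched.max(), gs.quenched.max()))
    prior = default_prior_box(gmax)
    prior.update({k: tuple(v) for k, v in (sec.get("prior") or {}).items()})
    fixed = dict(sec.get("fixed") or {})
    if sec.get("fixed_from_truth"):
        truth = {**ds.truth.get("population", {}), **ds.truth.get("measurement", {})}
        for name in sec["fixed_from_truth"]:
            fixed[name] = float(truth[name])
    fixed.pop("eta", None)
    af_gmfi = ds.autofluorescence.gmfi_Q()
    if ds.quench_control is not None:
        eta = estimate_quench_efficiency(
            ds.quench_control[0], ds.quench_control[1], af_gmfi
        )
    else:
        eta = float(sec.get("eta", 0.94))
    dcfg = cfg.discrepancy()
    wpath = cfg.outdir / "weights.yaml"
    if wpath.exists():
        with open(wpath) as fh:
            w = yaml.safe_load(fh)
        dcfg = replace(dcfg, w_ad=float(w["w_ad"]), w_corr=float(w["w_corr"]))
    return ABCProblem(obs=ds, prior=prior, fixed=fixed, eta=eta, cfg=dcfg)


# -- stages ------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig) -> None:
    seed = _stage_seed(cfg, "simulate")
    ds = generate_dataset(
        cfg.population(), cfg.measurement(), cfg.design(seed), cfg.af_model()
    )
    write_dataset(ds, cfg.outdir / "dataset")
    _append_manifest(cfg, "simulate", {"n_snapshots": len(ds.snapshots)})


def _stage_fit_gmfi(cfg: RunConfig) -> None:
    ds = _load_run_dataset(cfg)
    sec = cfg.section("fit_gmfi")
    af_gmfi = ds.autofluorescence.gmfi_Q()
    eta = estimate_quench_efficiency(
        ds.quench_control[0], ds.quench_control[1], af_gmfi
    )
    fit = fit_homogeneous(
        GmfiSeries.from_dataset(ds),
        E_Q=af_gmfi,
        eta=eta,
        starts=int(sec.get("starts", 20)),
        seed=_stage_seed(cfg, "fit-gmfi"),
    )
    fit.to_frame().to_csv(cfg.outdir / "gmfi_fit.csv", index=False)
    _append_manifest(
        cfg, "fit-gmfi",
        {"loglik": fit.loglik, "eta": eta,
         "surface_fraction": fit.surface_fraction()},
    )


def _stage_calibrate_weights(cfg: RunConfig) -> None:
    ds = _load_run_dataset(cfg)
    problem = _build_problem(cfg, ds)
    sec = cfg.section("calibrate_weights")
    dcfg = abc_mod.calibrate_weights(
        problem,
        n_pilot=int(sec.get("n_pilot", 50)),
        seed=_stage_seed(cfg, "calibrate-weights"),
    )
    with open(cfg.outdir / "weights.yaml", "w") as fh:
        yaml.safe_dump({"w_ad": dcfg.w_ad, "w_corr": dcfg.w_corr}, fh)
    _append_manifest(cfg, "calibrate-weights", {"w_corr": dcfg.w_corr})


def _stage_abc_smc(cfg: RunConfig) -> None:
    ds = _load_run_dataset(cfg)
    problem = _build_problem(cfg, ds)
    sec = cfg.section("abc").get("smc", {}) or {}
    res = abc_mod.abc_smc(
        problem,
        n_particles=int(sec.get("n_particles", 200)),
        target_quantile=float(sec.get("target_quantile", 0.5)),
        seed=_stage_seed(cfg, "abc-smc"),
        max_generations=int(sec.get("max_generations", 40)),
    )
    df = pd.DataFrame(res.particles, columns=list(problem.free))
    df["discrepancy"] = res.distances
    df.to_csv(cfg.outdir / "smc_particles.csv", index=False)
    with open(cfg.outdir / "smc.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "epsilon": float(res.epsilon),
                "theta_min": {n: float(v) for n, v in zip(problem.free, res.theta_min)},
                "n_generations": res.n_generations,
                "history": res.history,
            },
            fh,
        )
    _append_manifest(
        cfg, "abc-smc",
        {"epsilon": float(res.epsilon), "generations": res.n_generations},
    )


def _stage_abc_mcmc(cfg: RunConfig) -> None:
    ds = _load_run_dataset(cfg)
    problem = _build_problem(cfg, ds)
    with open(cfg.outdir / "smc.yaml") as fh:
        smc = yaml.safe_load(fh)
    particles = pd.read_csv(cfg.outdir / "smc_particles.csv")
    theta_init = np.array([smc["theta_min"][n] for n in problem.free])
    proposal_cov = np.cov(particles[list(problem.free)].to_numpy().T)
    proposal_cov = np.atleast_2d(proposal_cov)
    sec = cfg.section("abc").get("mcmc", {}) or {}
    chain = abc_mod.abc_mcmc(
        problem,
        epsilon=float(smc["epsilon"]),
        theta_init=theta_init,
        proposal_cov=proposal_cov,
        n_chains=int(sec.get("n_chains", 4)),
        n_steps=int(sec.get("n_steps", 25000)),
        thin=int(sec.get("thin", 100)),
        n_tune=int(sec.get("n_tune", 1000)),
        seed=np.random.SeedSequence(_stage_seed(cfg, "abc-mcmc")),
    )
    chain.to_csv(cfg.outdir / "chain.csv")
    _append_manifest(
        cfg, "abc-mcmc",
        {
            "epsilon": chain.epsilon,
            "acceptance_rate": chain.acceptance_rate,
            "ess": chain.ess,
            "rhat": chain.rhat,
        },
    )


def _load_chain(cfg: RunConfig) -> PosteriorChain:
    df = pd.read_csv(cfg.outdir / "chain.csv")
    with open(cfg.outdir / "run_manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    eps = manifest.get("abc-mcmc", {}).get("epsilon", np.nan)
    return PosteriorChain.from_frame(df, epsilon=eps)


def _stage_best_fit(cfg: RunConfig) -> None:
    ds = _load_run_dataset(cfg)
    problem = _build_problem(cfg, ds)
    chain = _load_chain(cfg)
    sec = cfg.section("abc").get("best_fit", {}) or {}
    theta = abc_mod.select_best_fit(
        problem,
        chain,
        n_candidates=int(sec.get("n_candidates", 400)),
        n_reps=int(sec.get("n_reps", 100)),
        seed=_stage_seed(cfg, "best-fit"),
    )
    with open(cfg.outdir / "best_fit.yaml", "w") as fh:
        yaml.safe_dump(
            {"theta": {n: float(v) for n, v in zip(problem.free, theta)}}, fh
        )
    _append_manifest(cfg, "best-fit", {})


def _stage_predict(cfg: RunConfig) -> None:
    ds = _load_run_dataset(cfg)
    problem = _build_problem(cfg, ds)
    with open(cfg.outdir / "best_fit.yaml") as fh:
        best = yaml.safe_load(fh)["theta"]
    full = dict(problem.fixed)
    full.update(best)
    sec = cfg.section("predict")
    seed = _stage_seed(cfg, "predict")
    times = [float(t) for t in sec.get("times", [10.0, 60.0, 120.0])]
    n_cells = int(sec.get("n_cells", 10000))
    frac = predict_mod.internal_fraction_distribution(
        full, times, n_cells=n_cells, seed=seed
    )
    pd.DataFrame(frac["samples"]).to_csv(
        cfg.outdir / "predict_internal_fraction.csv", index=False
    )
    s0, R = predict_mod.surface_fraction_distribution(full, n_cells=n_cells, seed=seed)
    pd.DataFrame({"s0": s0, "R": R}).to_csv(
        cfg.outdir / "predict_surface_fraction.csv", index=False
    )
    dep = predict_mod.between_time_dependence(
        full,
        float(sec.get("t_early", 10.0)),
        float(sec.get("t_late", 120.0)),
        n_cells=int(sec.get("n_dependence_cells", 1000)),
        seed=seed,
        eta=problem.eta,
    )
    pd.DataFrame({"q_early": dep.q_early, "q_late": dep.q_late}).to_csv(
        cfg.outdir / "predict_between_time.csv", index=False
    )
    info = {
        "gmfi_ratio": {str(k): float(v) for k, v in frac["gmfi_ratio"].items()},
        "between_time_copula_rho": None if dep.degenerate else float(dep.copula_rho),
    }
    with open(cfg.outdir / "predict_manifest.yaml", "w") as fh:
        yaml.safe_dump(info, fh)
    _append_manifest(cfg, "predict", info)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "fit-gmfi": _stage_fit_gmfi,
    "calibrate-weights": _stage_calibrate_weights,
    "abc-smc": _stage_abc_smc,
    "abc-mcmc": _stage_abc_mcmc,
    "best-fit": _stage_best_fit,
    "predict": _stage_predict,
}


def run_pipeline(cfg: RunConfig, stages=STAGES) -> dict[str, Path]:
    """Execute the requested stages in dependency order.

    Raises if a requested stage's dependency has neither been requested nor
    already produced its artifacts in the run directory.  Returns a mapping
    from stage name to its primary artifact path.
    """
    requested = [s for s in STAGES if s in stages]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    with open(cfg.outdir / "config_used.yaml", "w") as fh:
        yaml.safe_dump({"seed": cfg.seed, **cfg.raw}, fh)
    artifacts = {}
    for stage in requested:
        _require(cfg, stage)
        t0 = time.perf_counter()
        log.info("stage %s: starting", stage)
        _STAGE_FN[stage](cfg)
        dt = time.perf_counter() - t0
        log.info("stage %s: done in %.1fs", stage, dt)
        artifacts[stage] = cfg.outdir / _STAGE_ARTIFACTS[stage]
    return artifacts
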