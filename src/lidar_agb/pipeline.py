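"""End-to-end orchestration: simulate -> select -> fit -> predict ->
aggregate -> validate, with manifests for reproducibility.

Each stage writes its outputs plus a manifest recording the stage name,
a hash of the effective configuration, the derived stage seed and the
package version.  Reruns with an identical configuration and seed
reproduce outputs bit-for-bit; stages whose manifest already matches are
skipped, so a partial rerun resumes where it left off.  A single global
seed deterministically derives per-stage seeds by hashing the stage name,
so any stage can be rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .areal import mu_joint_estimate
from .model import (BiomassGeostatModel, BiomassGeostatResults, MCMCConfig,
                    PosteriorSamples, summarize_posterior)
from .selection import select_best
from .simulate import METRIC_NAMES, SimulationConfig, generate_scene
from .validation import compute_metrics, cv_run

logger = logging.getLogger(__name__)

STAGES = ["simulate", "select", "fit", "predict", "aggregate", "validate"]

_ALLOWED_KEYS = {
    "seed": None,
    "stages": None,
    "workdir": None,
    "simulate": {"n_plots", "domain_km", "sigma2", "tau2", "phi",
                 "target_correlations", "grid_shape", "seed"},
    "select": set(),
    "fit": {"kind", "n_iter", "n_burn", "thin"},
    "predict": {"mode"},
    "aggregate": {"pixel_area_ha"},
    "validate": {"k", "n_iter", "n_burn", "thin"},
}


class ConfigError(ValueError):
    pass


def validate_config(cfg: dict) -> dict:
    """Schema check; raises ConfigError listing every offending key."""
    bad = []
    for key, val in cfg.items():
        if key not in _ALLOWED_KEYS:
            bad.append(key)
            continue
        allowed = _ALLOWED_KEYS[key]
        if allowed is not None and isinstance(val, dict):
            bad.extend(f"{key}.{k}" for k in val if k not in allowed)
    if bad:
        raise ConfigError(f"unknown configuration keys: {sorted(bad)}")
    stages = cfg.get("stages", STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    return int((zlib.crc32(stage.encode()) ^ (global_seed & 0xFFFFFFFF))
               % (2 ** 31))


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _manifest_path(workdir: Path, stage: str) -> Path:
    return workdir / f"{stage}.manifest.json"


def _write_manifest(workdir: Path, stage: str, cfg_hash: str, seed: int,
                    outputs: list[str]) -> None:
    _write_json(_manifest_path(workdir, stage), {
        "stage": stage, "config_hash": cfg_hash, "seed": seed,
        "version": __version__, "outputs": outputs,
    })


def _stage_current(workdir: Path, stage: str, cfg_hash: str) -> bool:
    p = _manifest_path(workdir, stage)
    if not p.exists():
        return False
    try:
        man = json.loads(p.read_text())
    except json.JSONDecodeError:
        return False
    if man.get("config_hash") != cfg_hash:
        return False
    return all((workdir / f).exists() for f in man.get("outputs", []))


# -- stage implementations --------------------------------------------------

def run_simulate(cfg: dict, workdir: Path, seed: int) -> None:
    sc = cfg.get("simulate", {})
    sim = SimulationConfig(
        n_plots=sc.get("n_plots", 360),
        domain_km=tuple(sc.get("domain_km", (10.0, 10.0))),
        sigma2=sc.get("sigma2", 4.0), tau2=sc.get("tau2", 0.7),
        phi=sc.get("phi", 10.0),
        target_correlations=(tuple(sc["target_correlations"])
                             if "target_correlations" in sc else (0.74, 0.84, 0.85)),
        seed=sc.get("seed", seed))
    grid_shape = tuple(sc.get("grid_shape", (30, 30)))
    dataset, grid = generate_scene(sim, grid_shape=grid_shape)
    dataset.plots.to_csv(workdir / "plots.csv", index=False)
    dataset.metrics.to_csv(workdir / "metrics.csv", index=False)
    grid.table.to_csv(workdir / "grid.csv", index=False)
    _write_json(workdir / "truth.json", {
        "n_plots": sim.n_plots, "beta": list(sim.beta), "sigma2": sim.sigma2,
        "tau2": sim.tau2, "phi": sim.phi, "seed": sim.seed,
        "domain_km": list(sim.domain_km),
        "target_correlations": (list(sim.target_correlations)
                                if sim.target_correlations else None),
        "loadings": list(dataset.loadings),
        "cell_size_m": grid.cell_size_m,
    })


def run_select(cfg: dict, workdir: Path, seed: int) -> None:
    plots = pd.read_csv(workdir / "plots.csv")
    metrics = pd.read_csv(workdir / "metrics.csv")
    y = np.sqrt(plots["agb_mg_ha"].to_numpy(dtype=float))
    result = select_best(y, metrics, metric_names=list(METRIC_NAMES))
    result.to_frame().to_csv(workdir / "selection_ranking.csv", index=False)
    _write_json(workdir / "selection.json", {
        "best_metrics": result.best_subset(),
        "adjusted_r2": result.best.adjusted_r2,
        "r2": result.best.r2, "aic": result.best.aic,
    })


def _build_model(cfg: dict, workdir: Path) -> BiomassGeostatModel:
    plots = pd.read_csv(workdir / "plots.csv")
    kind = cfg.get("fit", {}).get("kind", "covariate")
    if kind == "null":
        return BiomassGeostatModel.from_dataframe(plots)
    metrics = pd.read_csv(workdir / "metrics.csv")
    sel = json.loads((workdir / "selection.json").read_text())
    return BiomassGeostatModel.from_dataframe(
        plots, metrics, metric_names=sel["best_metrics"])


def _mcmc_from_cfg(block: dict, seed: int) -> MCMCConfig:
    return MCMCConfig(n_iter=block.get("n_iter", 25_000),
                      n_burn=block.get("n_burn", 5_000),
                      thin=block.get("thin", 10), seed=seed)


def run_fit(cfg: dict, workdir: Path, seed: int) -> None:
    model = _build_model(cfg, workdir)
    res = model.fit(config=_mcmc_from_cfg(cfg.get("fit", {}), seed))
    s = res.samples
    draws = pd.DataFrame(s.beta, columns=s.beta_names)
    draws["sigma2"] = s.sigma2
    draws["tau2"] = s.tau2
    draws["phi"] = s.phi
    draws.to_csv(workdir / "draws.csv", index=False)
    table = summarize_posterior(s)
    _write_json(workdir / "fit_summary.json", {
        "kind": res.kind, "acceptance_rate": s.acceptance_rate,
        "n_draws": int(s.n_draws), "seed": seed,
        "metric_names": list(model.metric_names),
        "posterior": {str(k): {c: float(v) for c, v in row.items()}
                      for k, row in table.iterrows()},
    })


def load_results(cfg: dict, workdir: Path) -> BiomassGeostatResults:
    """Rebuild a results object from the fit stage's files."""
    model = _build_model(cfg, workdir)
    draws = pd.read_csv(workdir / "draws.csv")
    meta = json.loads((workdir / "fit_summary.json").read_text())
    beta_cols = [c for c in draws.columns if c.startswith("beta")]
    samples = PosteriorSamples(
        beta=draws[beta_cols].to_numpy(),
        sigma2=draws["sigma2"].to_numpy(), tau2=draws["tau2"].to_numpy(),
        phi=draws["phi"].to_numpy(), acceptance_rate=meta["acceptance_rate"],
        beta_names=beta_cols)
    fit_seed = meta["seed"]
    mcfg = MCMCConfig(seed=fit_seed)
    w_seed = np.random.SeedSequence(fit_seed).spawn(2)[1]
    return BiomassGeostatResults(model, samples, mcfg, w_seed)


def run_predict(cfg: dict, workdir: Path, seed: int) -> None:
    res = load_results(cfg, workdir)
    grid = pd.read_csv(workdir / "grid.csv")
    coords = grid[["x_km", "y_km"]].to_numpy(dtype=float)
    mode = cfg.get("predict", {}).get("mode", "independent")
    pred = res.predict(coords, grid, seed=seed, mode=mode)
    summary = pred.summary()
    summary.insert(0, "col", grid["col"])
    summary.insert(0, "row", grid["row"])
    summary.to_csv(workdir / "pixel_summary.csv", index=False)
    np.save(workdir / "pixel_agb_draws.npy", pred.agb_draws)


def run_aggregate(cfg: dict, workdir: Path, seed: int) -> None:
    grid = pd.read_csv(workdir / "grid.csv")
    agb_draws = np.load(workdir / "pixel_agb_draws.npy")
    cell_ha = (json.loads((workdir / "truth.json").read_text())["cell_size_m"]
               / 100.0) ** 2 if (workdir / "truth.json").exists() else None
    pixel_area = cfg.get("aggregate", {}).get("pixel_area_ha",
                                              cell_ha if cell_ha else 0.09)
    table = mu_joint_estimate(agb_draws, grid["mu_id"].to_numpy(),
                              pixel_area_ha=pixel_area)
    table.to_csv(workdir / "mu_estimates.csv", index=False)
    _write_json(workdir / "mu_estimates.json",
                {str(r["mu_id"]): {k: (float(v) if isinstance(v, (int, float, np.floating))
                                       else v)
                                   for k, v in r.items() if k != "mu_id"}
                 for r in table.to_dict("records")})


def run_validate(cfg: dict, workdir: Path, seed: int) -> None:
    plots = pd.read_csv(workdir / "plots.csv")
    metrics = pd.read_csv(workdir / "metrics.csv")
    sel = json.loads((workdir / "selection.json").read_text())
    block = cfg.get("validate", {})
    per_plot = cv_run(plots, metrics, metric_names=sel["best_metrics"],
                      mcmc=_mcmc_from_cfg(block, seed),
                      k=block.get("k", 10), seed=seed)
    per_plot.to_csv(workdir / "cv_per_plot.csv", index=False)
    report = compute_metrics(per_plot["obs"], per_plot["est"],
                             per_plot["ci_lo"], per_plot["ci_hi"])
    _write_json(workdir / "cv_report.json", report.to_dict())


_STAGE_FUNCS = {
    "simulate": (run_simulate, []),
    "select": (run_select, ["plots.csv", "metrics.csv"]),
    "fit": (run_fit, ["plots.csv"]),
    "predict": (run_predict, ["draws.csv", "grid.csv"]),
    "aggregate": (run_aggregate, ["pixel_agb_draws.npy", "grid.csv"]),
    "validate": (run_validate, ["plots.csv", "metrics.csv", "selection.json"]),
}

_STAGE_OUTPUTS = {
    "simulate": ["plots.csv", "metrics.csv", "grid.csv", "truth.json"],
    "select": ["selection_ranking.csv", "selection.json"],
    "fit": ["draws.csv", "fit_summary.json"],
    "predict": ["pixel_summary.csv", "pixel_agb_draws.npy"],
    "aggregate": ["mu_estimates.csv", "mu_estimates.json"],
    "validate": ["cv_per_plot.csv", "cv_report.json"],
}


def run_pipeline(config, workdir, force: bool = False) -> Path:
    """Run the configured stages in dependency order.

    ``config`` is a dict or a path to a YAML file.  Returns the workdir.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = validate_config(config)
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", STAGES)
    stages = [s for s in STAGES if s in stages]  # enforce dependency order

    for stage in stages:
        func, deps = _STAGE_FUNCS[stage]
        missing = [d for d in deps if not (workdir / d).exists()]
        block = {k: cfg.get(k) for k in ("seed", stage) if k in cfg}
        cfg_hash = _config_hash(block)
        if not force and _stage_current(workdir, stage, cfg_hash):
            logger.info("stage %s up to date; skipping", stage)
            continue
        if missing:
            raise FileNotFoundError(
                f"stage '{stage}' is missing upstream outputs: {missing}")
        s_seed = stage_seed(seed, stage)
        logger.info("running stage %s (seed %d)", stage, s_seed)
        func(cfg, workdir, s_seed)
        _write_manifest(workdir, stage, cfg_hash, s_seed,
                        _STAGE_OUTPUTS[stage])
    return workdir
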