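"""End-to-end pipeline: data -> fits -> calibration -> experiment -> analysis.

Every stage writes versioned outputs into the artifact directory plus a
manifest recording seeds and parameter provenance; re-running with the same
inputs, config and master seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import io as tio
from .config import PipelineConfig
from .dynamics import SimParams, calibrate_attack_coefficient
from .errors import ValidationError
from .experiment import run_experiment_grid, summarize_extinctions
from .fly_tpc import fit_fly_variant, fly_model_table
from .lmm import fit_extinction_lmm
from .synth import FlyDesign, WaspDesign, gen_fly_experiment, gen_wasp_experiment
from .wasp_glm import fit_wasp_variant, total_count_independence, wasp_model_table

log = logging.getLogger(__name__)

STAGES = ("data", "fit-fly", "fit-wasp", "calibrate", "experiment")


def sim_params_from_config(cfg: PipelineConfig, fits, t_p: float = 0.0) -> SimParams:
    """SimParams with gamma set so the realized growth multiplier
    gamma * r(t_base) under the G0-blind curve equals the configured
    growth target (the quantity the coexistence dynamics actually see)."""
    from .fly_tpc import tpc_mean

    r_base = float(tpc_mean(cfg.env.t_base, fits.fly_shared))
    if r_base <= 0:
        raise ValidationError("env.t_base", "no-TGE growth rate is zero at t_base")
    gamma = cfg.sim.growth_target / r_base
    return SimParams(gamma=gamma, t_p=t_p, K_H=cfg.sim.K_H, h=cfg.sim.h,
                     d=cfg.sim.d, k=cfg.sim.k,
                     extinction_threshold=cfg.sim.extinction_threshold)


def initial_state(cfg: PipelineConfig, params: SimParams, fits, model: str):
    """Initial (N0, P0): config override or the calibrated coexistence
    equilibrium at the burn-in temperature (fallback K_H/2, 10)."""
    from .dynamics import equilibrium_state

    if cfg.sim.N0 is not None and cfg.sim.P0 is not None:
        return cfg.sim.N0, cfg.sim.P0
    eq = equilibrium_state(params, fits, model=model, T=cfg.env.t_base)
    if eq is None:
        return cfg.sim.K_H / 2.0, 10.0
    return eq


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Execute all stages; halts with the failing stage named.

    Returns the artifact directory.  Outputs: data/*.csv, tables/*.csv,
    fits.json, calibration.json, results/*.csv, manifest.json, run.log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("tgepop")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest = {"config": cfg.to_dict(), "stages": [], "seeds": {"master": cfg.seed}}
    log.info("config echo: %s", json.dumps(cfg.to_dict(), sort_keys=True))
    current = None
    try:
        # -- stage 1: data ------------------------------------------------
        current = "data"
        ss = np.random.SeedSequence(cfg.seed)
        fly_seed, wasp_seed, exp_seed = (int(s % (2**31 - 1))
                                         for s in ss.generate_state(3, dtype=np.uint64))
        manifest["seeds"].update({"fly": fly_seed, "wasp": wasp_seed,
                                  "experiment": exp_seed})
        if cfg.fly_data:
            fly = tio.read_vial_csv(cfg.fly_data, "fly")
        else:
            fly = gen_fly_experiment(FlyDesign(
                vials_per_cell=cfg.synth.fly_vials_per_cell,
                dispersion=cfg.synth.fly_dispersion, seed=fly_seed))
        if cfg.wasp_data:
            wasp = tio.read_vial_csv(cfg.wasp_data, "wasp")
        else:
            wasp = gen_wasp_experiment(WaspDesign(
                vials_per_cell=cfg.synth.wasp_vials_per_cell,
                total_count_mean=cfg.synth.wasp_total_count_mean, seed=wasp_seed))
        tio.write_vial_csv(fly, out / "data" / "fly.csv")
        tio.write_vial_csv(wasp, out / "data" / "wasp.csv")
        manifest["stages"].append("data")

        # -- stage 2: fit-fly ---------------------------------------------
        current = "fit-fly"
        fly_table = fly_model_table(fly, n_starts=cfg.fit_n_starts, seed=fly_seed)
        (out / "tables").mkdir(exist_ok=True)
        fly_table.to_csv(out / "tables" / "fly_model_table.csv", index=False)
        fits = fly_table.attrs["fits"]
        fly_1b = fits.get("1b") or fit_fly_variant(fly, "1b", cfg.fit_n_starts, fly_seed)
        fly_1d = fits.get("1d") or fit_fly_variant(fly, "1d", cfg.fit_n_starts, fly_seed)
        manifest["stages"].append("fit-fly")

        # -- stage 3: fit-wasp ---------------------------------------------
        current = "fit-wasp"
        wasp_table = wasp_model_table(wasp)
        wasp_table.to_csv(out / "tables" / "wasp_model_table.csv", index=False)
        F, dfs, pval = total_count_independence(wasp)
        wfits = wasp_table.attrs["fits"]
        wasp_2a = wfits.get("2a") or fit_wasp_variant(wasp, "2a")
        wasp_2d = wfits.get("2d") or fit_wasp_variant(wasp, "2d")
        tio.save_fits(out / "fits.json", fly_1b, fly_1d, wasp_2a, wasp_2d,
                      extra={"total_count_independence":
                             {"F": F, "df": list(dfs), "p": pval}})
        manifest["stages"].append("fit-wasp")

        # -- stage 4: calibrate ---------------------------------------------
        current = "calibrate"
        bundle = tio.bundle_from_fits(fly_1b, fly_1d, wasp_2a, wasp_2d)
        calib = {}
        for model in cfg.experiment.models:
            params = sim_params_from_config(cfg, bundle)
            t_p = calibrate_attack_coefficient(
                params, bundle, model=model, T=cfg.env.t_base,
                n_gen=max(cfg.env.n_burn, 200))
            calib[model] = {"t_p": t_p, "gamma": params.gamma}
        (out / "calibration.json").write_text(json.dumps(calib, indent=2))
        manifest["stages"].append("calibrate")

        # -- stage 5: experiment + analysis ---------------------------------
        current = "experiment"
        (out / "results").mkdir(exist_ok=True)
        for model in cfg.experiment.models:
            params = dataclasses.replace(sim_params_from_config(cfg, bundle),
                                         t_p=calib[model]["t_p"])
            N0, P0 = initial_state(cfg, params, bundle, model)
            calib[model].update({"N0": N0, "P0": P0})
            grid = run_experiment_grid(
                bundle, params, model=model, n_seeds=cfg.experiment.n_seeds,
                master_seed=exp_seed, rhos=cfg.env.rhos, N0=N0,
                P0=P0, sigma=cfg.env.sigma, t_base=cfg.env.t_base,
                warming=cfg.env.warming, n_burn=cfg.env.n_burn,
                n_ramp=cfg.env.n_ramp, cap=cfg.env.cap)
            grid.to_csv(out / "results" / f"extinctions_model{model}.csv", index=False)
            summarize_extinctions(grid).to_csv(
                out / "results" / f"summary_model{model}.csv", index=False)
            anova = fit_extinction_lmm(grid)
            anova.to_csv(out / "results" / f"anova_model{model}.csv", index=False)
        (out / "calibration.json").write_text(json.dumps(calib, indent=2))
        manifest["stages"].append("experiment")
    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        root.removeHandler(handler)
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    root.removeHandler(handler)
    handler.close()
    return out
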