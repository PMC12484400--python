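"""Tabular I/O: vial-level CSVs and JSON serialization of fitted objects.

All tabular files are plain UTF-8 CSV with a header row, one vial per
line.  Fitted parameters travel as JSON so a simulation can be rebuilt
from fit artifacts without refitting.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dynamics import FitBundle
from .errors import VialDataError
from .fly_tpc import FlyFitResult, FlyParams, TPCParams
from .interpolate import InterpolatedFlyTPC, InterpolatedWaspEta
from .wasp_glm import WaspFitResult, WaspLogitCoeffs

FLY_COLUMNS = ["g0_temp", "g1_temp", "count"]
WASP_COLUMNS = ["g0_temp", "g1_temp", "wasp_count", "fly_count"]
G0_LEVELS = {19.0, 23.0, 27.0}
G1_LEVELS = {19.0, 21.0, 23.0, 25.0, 27.0}


def _is_count(x) -> bool:
    return np.isfinite(x) and float(x) >= 0 and float(x) == int(x)


def read_vial_csv(path, schema: str, lenient: bool = False) -> pd.DataFrame:
    """Read and validate a fly or wasp vial table.

    Malformed rows are reported with their 1-based file line numbers
    (header is line 1).  Unless ``lenient``, temperatures must match the
    experimental levels.
    """
    if schema not in ("fly", "wasp"):
        raise VialDataError(f"unknown schema {schema!r}")
    cols = FLY_COLUMNS if schema == "fly" else WASP_COLUMNS
    path = Path(path)
    if not path.exists():
        raise VialDataError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise VialDataError(f"{path}: missing column(s) {missing}")
    df = df[cols]
    bad: list = []
    count_cols = cols[2:]
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        g0, g1 = float(row[0]), float(row[1])
        counts_ok = all(_is_count(getattr(row, c)) for c in count_cols)
        temps_ok = lenient or (g0 in G0_LEVELS and g1 in G1_LEVELS)
        if not (counts_ok and temps_ok and np.isfinite(g0) and np.isfinite(g1)):
            bad.append(line)
    if bad:
        raise VialDataError(
            f"{path}: {len(bad)} malformed row(s) at line(s) {bad[:20]}"
            + ("..." if len(bad) > 20 else ""), lines=bad)
    for c in count_cols:
        df[c] = df[c].astype(int)
    for c in cols[:2]:
        df[c] = df[c].astype(float)
    return df


def write_vial_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------- JSON fits

def _tpc_to_dict(p: TPCParams) -> dict:
    return {"topt": p.topt, "rmax": p.rmax, "a": p.a, "ctmax": p.ctmax,
            "theta": p.theta}


def fly_fit_to_dict(fit: FlyFitResult) -> dict:
    return {
        "variant": fit.variant,
        "theta": fit.params.theta,
        "by_g0": {f"{g:g}": _tpc_to_dict(p) for g, p in fit.params.by_g0.items()},
        "loglik": fit.loglik, "n_params": fit.n_params, "aic": fit.aic,
        "coeffs": fit.coeffs,
    }


def fly_fit_from_dict(d: dict) -> FlyFitResult:
    by_g0 = {float(g): TPCParams(**{k: v for k, v in p.items()})
             for g, p in d["by_g0"].items()}
    params = FlyParams(by_g0=by_g0, theta=d["theta"])
    return FlyFitResult(variant=d["variant"], params=params, loglik=d["loglik"],
                        n_params=d["n_params"], aic=d["aic"],
                        coeffs=d.get("coeffs", {}))


def wasp_fit_to_dict(fit: WaspFitResult) -> dict:
    return {
        "variant": fit.variant,
        "by_g0": {f"{g:g}": [c.intercept, c.slope]
                  for g, c in fit.coeffs_by_g0.items()},
        "shared": ([fit.coeffs.intercept, fit.coeffs.slope]
                   if fit.coeffs is not None else None),
        "beta": fit.beta, "loglik": fit.loglik,
        "n_params": fit.n_params, "aic": fit.aic,
    }


def wasp_fit_from_dict(d: dict) -> WaspFitResult:
    by_g0 = {float(g): WaspLogitCoeffs(*v) for g, v in d["by_g0"].items()}
    shared = WaspLogitCoeffs(*d["shared"]) if d.get("shared") else None
    return WaspFitResult(variant=d["variant"], coeffs_by_g0=by_g0, coeffs=shared,
                         beta=d.get("beta", {}), loglik=d["loglik"],
                         n_params=d["n_params"], aic=d["aic"])


def save_fits(path, fly_1b: FlyFitResult, fly_1d: FlyFitResult,
              wasp_2a: WaspFitResult, wasp_2d: WaspFitResult,
              extra: Optional[dict] = None) -> None:
    payload = {"fly_1b": fly_fit_to_dict(fly_1b), "fly_1d": fly_fit_to_dict(fly_1d),
               "wasp_2a": wasp_fit_to_dict(wasp_2a), "wasp_2d": wasp_fit_to_dict(wasp_2d)}
    if extra:
        payload.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2))


def load_fit_bundle(path) -> FitBundle:
    """Rebuild the simulator's :class:`FitBundle` from a fits JSON file."""
    d = json.loads(Path(path).read_text())
    fly_1b = fly_fit_from_dict(d["fly_1b"])
    fly_1d = fly_fit_from_dict(d["fly_1d"])
    wasp_2a = wasp_fit_from_dict(d["wasp_2a"])
    wasp_2d = wasp_fit_from_dict(d["wasp_2d"])
    shared = next(iter(fly_1b.params.by_g0.values()))
    shared = dataclasses.replace(shared, theta=fly_1b.params.theta)
    return FitBundle(
        fly_shared=shared,
        fly_itp=InterpolatedFlyTPC.from_fit(fly_1d),
        wasp_shared=wasp_2a.coeffs,
        wasp_itp=InterpolatedWaspEta.from_fit(wasp_2d),
    )


def bundle_from_fits(fly_1b: FlyFitResult, fly_1d: FlyFitResult,
                     wasp_2a: WaspFitResult, wasp_2d: WaspFitResult) -> FitBundle:
    shared = next(iter(fly_1b.params.by_g0.values()))
    shared = dataclasses.replace(shared, theta=fly_1b.params.theta)
    return FitBundle(
        fly_shared=shared,
        fly_itp=InterpolatedFlyTPC.from_fit(fly_1d),
        wasp_shared=wasp_2a.coeffs,
        wasp_itp=InterpolatedWaspEta.from_fit(wasp_2d),
    )
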