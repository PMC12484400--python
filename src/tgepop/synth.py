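"""Synthetic vial-level data generators for both factorial experiments.

The generators emulate the statistical structure the fitting stages assume:
a 3 x 5 factorial of parental (G0 in {19, 23, 27} C) and offspring
(G1 in {19, 21, 23, 25, 27} C) temperatures, with

* fly experiment: ~40 vials per cell, counts negative-binomial around a
  per-G0 thermal performance curve with a shared dispersion theta;
* wasp experiment: 16-20 vials per cell, a Poisson total emergence count
  whose mean is independent of G1, split binomially into wasps and flies
  with a logit-linear-in-G1 wasp share per G0.

The default "true" parameters are invented test values chosen to mimic the
qualitative ordering seen in the real system (intermediate parental
temperature best for flies, parental-offspring temperature matching best
for wasps); they are not estimates.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Mapping, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError
from .fly_tpc import TPCParams, tpc_mean
from .wasp_glm import WaspLogitCoeffs

G0_LEVELS = (19.0, 23.0, 27.0)
G1_LEVELS = (19.0, 21.0, 23.0, 25.0, 27.0)


def default_fly_true_params() -> Dict[float, TPCParams]:
    return {
        19.0: TPCParams(topt=25.5, rmax=22.0, a=6.0),
        23.0: TPCParams(topt=27.0, rmax=38.0, a=7.0),
        27.0: TPCParams(topt=26.0, rmax=12.0, a=8.0),
    }


def default_wasp_true_coeffs() -> Dict[float, WaspLogitCoeffs]:
    # Declining wasp share in G1 after a cool parental generation, rising
    # after a hot one (parent-offspring matching), flat-ish in between.
    return {
        19.0: WaspLogitCoeffs(6.0, -0.22),
        23.0: WaspLogitCoeffs(0.2, 0.04),
        27.0: WaspLogitCoeffs(-7.0, 0.32),
    }


def _check_temps(field, temps):
    arr = np.asarray(list(temps), dtype=float)
    if arr.size == 0 or not np.all((arr >= 0) & (arr <= 40)):
        raise ValidationError(field, f"temperatures must lie in [0, 40], got {list(temps)}")


@dataclasses.dataclass
class FlyDesign:
    """Design of the fly reproduction experiment."""

    g0_levels: tuple = G0_LEVELS
    g1_levels: tuple = G1_LEVELS
    vials_per_cell: int = 40
    true_params: Mapping[float, TPCParams] = dataclasses.field(
        default_factory=default_fly_true_params)
    dispersion: float = 1.5
    seed: int = 0

    def validate(self):
        _check_temps("g0_levels", self.g0_levels)
        _check_temps("g1_levels", self.g1_levels)
        if not (isinstance(self.vials_per_cell, (int, np.integer)) and self.vials_per_cell >= 1):
            raise ValidationError("vials_per_cell", f"must be an integer >= 1, got {self.vials_per_cell}")
        for g in self.g0_levels:
            if float(g) not in {float(k) for k in self.true_params}:
                raise ValidationError("true_params", f"missing entry for g0 level {g}")
        if not self.dispersion > 0:
            raise ValidationError("dispersion", f"must be > 0, got {self.dispersion}")


@dataclasses.dataclass
class WaspDesign:
    """Design of the wasp reproductive-output experiment."""

    g0_levels: tuple = G0_LEVELS
    g1_levels: tuple = G1_LEVELS
    #: int, or mapping (g0, g1) -> int to reproduce uneven replication.
    vials_per_cell: Union[int, Mapping] = 18
    total_count_mean: float = 90.0
    true_coeffs: Mapping[float, WaspLogitCoeffs] = dataclasses.field(
        default_factory=default_wasp_true_coeffs)
    seed: int = 0

    def cell_n(self, g0, g1) -> int:
        if isinstance(self.vials_per_cell, Mapping):
            return int(self.vials_per_cell[(g0, g1)])
        return int(self.vials_per_cell)

    def validate(self):
        _check_temps("g0_levels", self.g0_levels)
        _check_temps("g1_levels", self.g1_levels)
        for g0 in self.g0_levels:
            for g1 in self.g1_levels:
                try:
                    n = self.cell_n(g0, g1)
                except KeyError:
                    raise ValidationError("vials_per_cell", f"no replication given for cell ({g0}, {g1})")
                if n < 1:
                    raise ValidationError("vials_per_cell", f"must be >= 1, got {n} for cell ({g0}, {g1})")
        if not self.total_count_mean > 0:
            raise ValidationError("total_count_mean", f"must be > 0, got {self.total_count_mean}")
        for g in self.g0_levels:
            if float(g) not in {float(k) for k in self.true_coeffs}:
                raise ValidationError("true_coeffs", f"missing entry for g0 level {g}")


def gen_fly_experiment(design: FlyDesign) -> pd.DataFrame:
    """One row per (g0, g1, vial) with a negative-binomial emergence count.

    Counts are drawn as a gamma-Poisson mixture (shape = theta,
    mean = mu), the exact NB(mean mu, size theta) and numerically safe for
    very large theta (Poisson limit).  Identical design+seed reproduces the
    dataset exactly.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    theta = design.dispersion
    rows = []
    for g0 in design.g0_levels:
        p = design.true_params[float(g0)]
        for g1 in design.g1_levels:
            mu = tpc_mean(float(g1), p)
            lam = rng.gamma(shape=theta, scale=max(mu, 1e-12) / theta,
                            size=design.vials_per_cell)
            counts = rng.poisson(lam)
            for c in counts:
                rows.append((float(g0), float(g1), int(c)))
    return pd.DataFrame(rows, columns=["g0_temp", "g1_temp", "count"])


def gen_wasp_experiment(design: WaspDesign) -> pd.DataFrame:
    """One row per vial: Poisson total emergences split binomially.

    The total's mean is independent of G1 (the assumption the proportion
    model rests on); the wasp share is inverse-logit(intercept + slope*g1)
    for that vial's parental temperature.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    rows = []
    for g0 in design.g0_levels:
        c = design.true_coeffs[float(g0)]
        for g1 in design.g1_levels:
            n = design.cell_n(g0, g1)
            totals = rng.poisson(design.total_count_mean, size=n)
            p = expit(c.intercept + c.slope * float(g1))
            wasps = rng.binomial(totals, p)
            for tot, w in zip(totals, wasps):
                rows.append((float(g0), float(g1), int(w), int(tot - w)))
    return pd.DataFrame(rows, columns=["g0_temp", "g1_temp", "wasp_count", "fly_count"])
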