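"""Thermal performance curves for host (fly) reproduction, fit to vial counts.

The reproductive output of a vial is modelled with a classic asymmetric
thermal performance curve (TPC): a Gaussian rise up to the thermal optimum
``Topt`` followed by a quadratic fall to zero at the critical maximum
``CTmax``::

    mu(T) = Rmax * exp(-((T - Topt) / (2 a))**2)                   T <= Topt
    mu(T) = Rmax * (1 - ((T - Topt) / (Topt - CTmax))**2)          T >  Topt

``Rmax`` is the expected number of emergences per vial at the optimum and
``a`` is a curve-width parameter (degrees C).  ``CTmax`` is held fixed at
30 C, outside the experimental range.  Counts are overdispersed, so the
likelihood is negative binomial with mean ``mu(T)`` and a single shared
size (dispersion) parameter ``theta`` (variance ``mu + mu**2/theta``).

Seven model variants encode how the parental-generation (G0) temperature
enters the curve, from fully shared parameters to fully G0-specific ones;
they are compared by AIC.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

from .errors import FitConvergenceError, ValidationError

CTMAX_DEFAULT = 30.0
#: Floor applied to a non-positive predicted mean before the log-likelihood.
MEAN_FLOOR = 1e-6
#: Numerical floor on the width parameter to avoid division blow-ups.
A_FLOOR = 1e-3

VARIANTS = ("1a", "1b", "1c", "1d", "1e", "1f", "1g")

# Which of the three curve parameters get a separate value per G0 level.
_PER_G0 = {
    "1a": (),
    "1b": (),
    "1d": ("topt", "rmax", "a"),
    "1e": ("rmax", "a"),
    "1f": ("topt", "a"),
    "1g": ("topt", "rmax"),
}

_TOPT_BOUNDS = (15.0, 29.9)
_LOG_RMAX_BOUNDS = (np.log(0.1), np.log(500.0))
_LOG_A_BOUNDS = (np.log(0.5), np.log(50.0))
_LOG_THETA_BOUNDS = (np.log(0.01), np.log(1e4))


@dataclasses.dataclass(frozen=True)
class TPCParams:
    """Parameters of one thermal performance curve.

    theta is carried here for convenience when a curve is used on its own;
    within a multi-G0 model the dispersion is a single shared parameter and
    lives on :class:`FlyParams`.
    """

    topt: float
    rmax: float
    a: float
    ctmax: float = CTMAX_DEFAULT
    theta: Optional[float] = None

    def __post_init__(self):
        if not np.isfinite(self.topt) or self.topt >= self.ctmax:
            raise ValidationError("topt", f"must be finite and < ctmax={self.ctmax}, got {self.topt}")
        if not self.rmax > 0:
            raise ValidationError("rmax", f"must be > 0, got {self.rmax}")
        if not self.a > 0:
            raise ValidationError("a", f"must be > 0, got {self.a}")
        if self.theta is not None and not self.theta > 0:
            raise ValidationError("theta", f"must be > 0, got {self.theta}")


def _deutsch(T, topt, rmax, a, ctmax=CTMAX_DEFAULT):
    """Vectorized TPC; operates on raw arrays (no validation, no floors)."""
    T = np.asarray(T, dtype=float)
    a = np.maximum(a, A_FLOOR)
    cold = rmax * np.exp(-(((T - topt) / (2.0 * a)) ** 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        hot = rmax * (1.0 - ((T - topt) / (topt - ctmax)) ** 2)
    out = np.where(T <= topt, cold, hot)
    out = np.where(T >= ctmax, 0.0, out)
    return np.maximum(out, 0.0)


def tpc_mean(T, p: TPCParams):
    """Expected emergences per vial at test temperature ``T`` (degrees C).

    Continuous at ``Topt`` (both branches equal ``Rmax``) and clamped to 0
    at and beyond ``CTmax`` where the raw quadratic would go negative.
    """
    out = _deutsch(T, p.topt, p.rmax, p.a, p.ctmax)
    if np.isscalar(T) or np.ndim(T) == 0:
        return float(out)
    return out


@dataclasses.dataclass
class FlyParams:
    """A full parameter set for one model variant.

    by_g0 maps each parental temperature level to its effective curve;
    theta is the shared negative-binomial size (None means Poisson).
    """

    by_g0: Mapping[float, TPCParams]
    theta: Optional[float] = None


def _mu_for(data: pd.DataFrame, params: FlyParams) -> np.ndarray:
    g1 = data["g1_temp"].to_numpy(dtype=float)
    g0 = data["g0_temp"].to_numpy(dtype=float)
    mu = np.empty(len(data), dtype=float)
    for level, p in params.by_g0.items():
        mask = g0 == float(level)
        if mask.any():
            mu[mask] = _deutsch(g1[mask], p.topt, p.rmax, p.a, p.ctmax)
    missing = ~np.isin(g0, [float(k) for k in params.by_g0])
    if missing.any():
        raise ValidationError("g0_temp", f"no parameters for G0 level(s) {sorted(set(g0[missing]))}")
    return mu


def _count_loglik(counts: np.ndarray, mu: np.ndarray, theta: Optional[float]) -> float:
    """Sum of per-vial log-pmfs; mean floored at MEAN_FLOOR (no warning)."""
    mu = np.maximum(mu, MEAN_FLOOR)
    if theta is None:
        return float(stats.poisson.logpmf(counts, mu).sum())
    p = theta / (theta + mu)
    return float(stats.nbinom.logpmf(counts, theta, p).sum())


def nb_loglik(data: pd.DataFrame, params: FlyParams) -> float:
    """Log-likelihood of vial counts under the TPC count model.

    Negative binomial with shared size ``params.theta`` (Poisson when
    theta is None, i.e. variant 1a).  A predicted mean <= 0 -- possible
    only when the data contain temperatures at or above CTmax -- is
    floored at ``MEAN_FLOOR`` with a warning.
    """
    counts = data["count"].to_numpy()
    if (counts < 0).any():
        raise ValidationError("count", "negative counts in data")
    mu = _mu_for(data, params)
    if (mu < MEAN_FLOOR).any():
        warnings.warn(
            f"{int((mu < MEAN_FLOOR).sum())} vial(s) with predicted mean <= 0 "
            f"floored at {MEAN_FLOOR}", RuntimeWarning, stacklevel=2,
        )
    return _count_loglik(counts, mu, params.theta)


@dataclasses.dataclass
class FlyFitResult:
    variant: str
    params: FlyParams
    loglik: float
    n_params: int
    aic: float
    #: Raw optimizer vector, labelled, for serialization / diagnostics.
    coeffs: Dict[str, float] = dataclasses.field(default_factory=dict)
    converged: bool = True


class _VariantCoder:
    """Maps a flat optimizer vector to FlyParams for one model variant."""

    def __init__(self, variant: str, g0_levels: Sequence[float]):
        if variant not in VARIANTS:
            raise ValidationError("variant", f"unknown variant {variant!r}")
        self.variant = variant
        self.g0_levels = [float(g) for g in sorted(g0_levels)]
        self.poisson = variant == "1a"
        self.labels: list = []
        self.bounds: list = []
        if variant == "1c":
            # Each curve parameter an affine function of G0 (centred at 23 C
            # for conditioning); Rmax and a affine on the natural scale.
            for name, b0, b1 in (
                ("topt", _TOPT_BOUNDS, (-2.0, 2.0)),
                ("rmax", (0.1, 500.0), (-60.0, 60.0)),
                ("a", (0.5, 50.0), (-6.0, 6.0)),
            ):
                self.labels += [f"{name}_23", f"{name}_slope"]
                self.bounds += [b0, b1]
        else:
            per = _PER_G0[variant]
            for name, b in (("topt", _TOPT_BOUNDS), ("log_rmax", _LOG_RMAX_BOUNDS),
                            ("log_a", _LOG_A_BOUNDS)):
                base = name.replace("log_", "")
                if base in per:
                    for g in self.g0_levels:
                        self.labels.append(f"{name}_{g:g}")
                        self.bounds.append(b)
                else:
                    self.labels.append(name)
                    self.bounds.append(b)
        if not self.poisson:
            self.labels.append("log_theta")
            self.bounds.append(_LOG_THETA_BOUNDS)
        self.n_params = len(self.labels)

    def decode(self, x: np.ndarray) -> FlyParams:
        x = np.asarray(x, dtype=float)
        theta = None if self.poisson else float(np.exp(x[-1]))
        by_g0: Dict[float, TPCParams] = {}
        if self.variant == "1c":
            t0, t1, r0, r1, a0, a1 = x[:6]
            for g in self.g0_levels:
                dg = g - 23.0
                by_g0[g] = TPCParams(
                    topt=min(t0 + t1 * dg, CTMAX_DEFAULT - 0.05),
                    rmax=max(r0 + r1 * dg, MEAN_FLOOR),
                    a=max(a0 + a1 * dg, A_FLOOR),
                )
        else:
            per = _PER_G0[self.variant]
            i = 0
            vals: Dict[str, Dict[float, float]] = {}
            for name in ("topt", "rmax", "a"):
                vals[name] = {}
                if name in per:
                    for g in self.g0_levels:
                        vals[name][g] = x[i]
                        i += 1
                else:
                    for g in self.g0_levels:
                        vals[name][g] = x[i]
                    i += 1
            for g in self.g0_levels:
                by_g0[g] = TPCParams(
                    topt=vals["topt"][g],
                    rmax=float(np.exp(vals["rmax"][g])),
                    a=float(np.exp(vals["a"][g])),
                )
        return FlyParams(by_g0=by_g0, theta=theta)

    def smart_start(self, data: pd.DataFrame) -> np.ndarray:
        """Moment-based starting point from per-cell means."""
        cell = data.groupby(["g0_temp", "g1_temp"])["count"].mean()
        pooled = data.groupby("g1_temp")["count"].mean()

        def curve_guess(means: pd.Series):
            topt = float(np.clip(means.idxmax() + 0.5, *_TOPT_BOUNDS))
            rmax = float(np.clip(means.max(), 0.5, 400.0))
            return topt, rmax, 5.0

        m = data["count"].mean()
        v = data["count"].var()
        theta0 = float(np.clip(m**2 / max(v - m, 1e-3), 0.05, 100.0))
        if self.variant == "1c":
            topt, rmax, a = curve_guess(pooled)
            x = [topt, 0.0, rmax, 0.0, a, 0.0]
        else:
            per = _PER_G0[self.variant]
            x = []
            for name in ("topt", "rmax", "a"):
                if name in per:
                    for g in self.g0_levels:
                        topt, rmax, a = curve_guess(cell.loc[g])
                        val = {"topt": topt, "rmax": np.log(rmax), "a": np.log(a)}[name]
                        x.append(val)
                else:
                    topt, rmax, a = curve_guess(pooled)
                    x.append({"topt": topt, "rmax": np.log(rmax), "a": np.log(a)}[name])
        if not self.poisson:
            x.append(np.log(theta0))
        x = np.asarray(x, dtype=float)
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip(x, lo + 1e-6, hi - 1e-6)


def fit_fly_variant(
    data: pd.DataFrame,
    variant: str,
    n_starts: int = 20,
    seed: int = 0,
) -> FlyFitResult:
    """Maximum-likelihood fit of one model variant.

    Uses bounded L-BFGS-B from a moment-based start plus ``n_starts``
    Latin-hypercube restarts (TPC likelihoods are multimodal); positivity of
    Rmax, a and theta is enforced through log transforms.  Raises
    :class:`FitConvergenceError` carrying the best-so-far result if no
    restart converges.
    """
    if len(data) == 0:
        raise ValidationError("data", "empty dataset")
    g0_levels = sorted(data["g0_temp"].unique())
    if _PER_G0.get(variant) or variant == "1c":
        per_g1 = data.groupby("g0_temp")["g1_temp"].nunique()
        if (per_g1 < 2).any():
            raise ValidationError("data", "need >= 2 distinct G1 levels per G0 level")
    coder = _VariantCoder(variant, g0_levels)
    counts = data["count"].to_numpy()

    def neg_loglik(x):
        params = coder.decode(x)
        mu = _mu_for(data, params)
        ll = _count_loglik(counts, mu, params.theta)
        return -ll if np.isfinite(ll) else 1e12

    lo = np.array([b[0] for b in coder.bounds])
    hi = np.array([b[1] for b in coder.bounds])
    sampler = qmc.LatinHypercube(d=coder.n_params, seed=seed)
    starts = [coder.smart_start(data)]
    starts += list(lo + sampler.random(n_starts) * (hi - lo))

    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(
            neg_loglik, x0, method="L-BFGS-B", bounds=coder.bounds,
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 1000},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_success:
        raise FitConvergenceError(
            f"variant {variant}: no restart converged", diagnostics=best,
        )
    params = coder.decode(best.x)
    loglik = -float(best.fun)
    aic = 2.0 * coder.n_params - 2.0 * loglik
    coeffs = dict(zip(coder.labels, [float(v) for v in best.x]))
    return FlyFitResult(
        variant=variant, params=params, loglik=loglik,
        n_params=coder.n_params, aic=aic, coeffs=coeffs,
    )


def fly_model_table(
    data: pd.DataFrame,
    variants: Sequence[str] = VARIANTS,
    n_starts: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the requested variants and tabulate loglik / n_params / AIC / dAIC.

    Per-variant fit failures are recorded in an ``error`` column without
    aborting the table.  Rows are ordered by AIC with ties broken by fewer
    parameters, then variant id.
    """
    rows = []
    fits: Dict[str, FlyFitResult] = {}
    for v in variants:
        try:
            fit = fit_fly_variant(data, v, n_starts=n_starts, seed=seed)
            fits[v] = fit
            rows.append({"variant": v, "n_params": fit.n_params,
                         "loglik": fit.loglik, "aic": fit.aic, "error": ""})
        except Exception as exc:  # noqa: BLE001 -- table must survive per-variant failure
            rows.append({"variant": v, "n_params": np.nan, "loglik": np.nan,
                         "aic": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows)
    best_aic = table["aic"].min()
    table["delta_aic"] = table["aic"] - best_aic
    table = table.sort_values(
        by=["aic", "n_params", "variant"], kind="mergesort"
    ).reset_index(drop=True)
    table.attrs["fits"] = fits
    return table
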