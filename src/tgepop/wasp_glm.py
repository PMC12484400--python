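"""Binomial logit models for the parasitoid (wasp) share of emergences.

Each vial yields a pair (wasp_count, fly_count); the proportion of wasps
among all emerged insects is modelled as binomial with success probability
logit-linear in the offspring-generation temperature G1.  Four variants
encode how the parental temperature G0 enters: not at all (2a), as a linear
main effect (2b), with a G0 x G1 interaction, G0 numeric (2c), or as a
three-level factor with separate per-G0 intercept and slope (2d, fit as
three independent GLMs whose log-likelihoods sum).

Using the proportion assumes the combined count per vial is independent of
G1 temperature; :func:`total_count_independence` provides the supporting
OLS regression test.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .errors import SeparationError, ValidationError

try:  # statsmodels moved/renamed this exception across versions
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    PerfectSeparationError = RuntimeError

VARIANTS = ("2a", "2b", "2c", "2d")
_N_PARAMS = {"2a": 2, "2b": 3, "2c": 4, "2d": 6}


@dataclasses.dataclass(frozen=True)
class WaspLogitCoeffs:
    """Intercept and per-degree-C slope on the logit scale."""

    intercept: float
    slope: float

    def __post_init__(self):
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValidationError("coeffs", "intercept and slope must be finite")


CoeffsLike = Union[WaspLogitCoeffs, Mapping[float, WaspLogitCoeffs]]


def logistic_eta(T, c: WaspLogitCoeffs):
    """Modelled wasp proportion eta(T) = inverse-logit(intercept + slope*T)."""
    out = expit(c.intercept + c.slope * np.asarray(T, dtype=float))
    if np.ndim(T) == 0:
        return float(out)
    return out


def _p_for(data: pd.DataFrame, coeffs: CoeffsLike) -> np.ndarray:
    g1 = data["g1_temp"].to_numpy(dtype=float)
    if isinstance(coeffs, WaspLogitCoeffs):
        return expit(coeffs.intercept + coeffs.slope * g1)
    g0 = data["g0_temp"].to_numpy(dtype=float)
    p = np.empty(len(data), dtype=float)
    seen = np.zeros(len(data), dtype=bool)
    for level, c in coeffs.items():
        mask = g0 == float(level)
        p[mask] = expit(c.intercept + c.slope * g1[mask])
        seen |= mask
    if not seen.all():
        raise ValidationError("g0_temp", f"no coefficients for G0 level(s) {sorted(set(g0[~seen]))}")
    return p


def binom_loglik(data: pd.DataFrame, coeffs: CoeffsLike) -> float:
    """Binomial log-likelihood of the wasp/total splits.

    ``coeffs`` is either a single :class:`WaspLogitCoeffs` (shared model) or
    a mapping G0 level -> coefficients.  Vials with zero total emergences
    contribute 0 (the log of the single certain outcome).
    """
    wasp = data["wasp_count"].to_numpy()
    total = wasp + data["fly_count"].to_numpy()
    if (wasp > total).any() or (wasp < 0).any() or (total < 0).any():
        raise ValidationError("wasp_count", "counts must satisfy 0 <= wasp_count <= total")
    p = _p_for(data, coeffs)
    ll = stats.binom.logpmf(wasp, total, p)
    return float(np.where(total == 0, 0.0, ll).sum())


@dataclasses.dataclass
class WaspFitResult:
    variant: str
    #: Effective (intercept, slope) per G0 level; for 2a all levels share.
    coeffs_by_g0: Dict[float, WaspLogitCoeffs]
    #: Shared coefficients (variant 2a only, else None).
    coeffs: Optional[WaspLogitCoeffs]
    #: Raw regression coefficients, labelled.
    beta: Dict[str, float]
    loglik: float
    n_params: int
    aic: float


def _glm_fit(endog, exog):
    try:
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(tol=1e-10)
    except PerfectSeparationError as exc:
        raise SeparationError(f"perfect separation in binomial GLM: {exc}") from exc
    if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 1e3:
        raise SeparationError(
            f"binomial GLM diverged (coefficients {res.params}); "
            "likely quasi-complete separation"
        )
    return res


def fit_wasp_variant(data: pd.DataFrame, variant: str) -> WaspFitResult:
    """ML fit of one wasp-proportion model variant via IRLS."""
    if variant not in VARIANTS:
        raise ValidationError("variant", f"unknown variant {variant!r}")
    wasp = data["wasp_count"].to_numpy(dtype=float)
    fly = data["fly_count"].to_numpy(dtype=float)
    endog = np.column_stack([wasp, fly])
    g1 = data["g1_temp"].to_numpy(dtype=float)
    g0 = data["g0_temp"].to_numpy(dtype=float)
    levels = sorted(set(g0))

    if variant == "2d":
        coeffs_by_g0 = {}
        beta = {}
        loglik = 0.0
        for lev in levels:
            m = g0 == lev
            res = _glm_fit(endog[m], sm.add_constant(g1[m]))
            b0, b1 = (float(v) for v in res.params)
            coeffs_by_g0[lev] = WaspLogitCoeffs(b0, b1)
            beta[f"intercept_{lev:g}"] = b0
            beta[f"slope_{lev:g}"] = b1
            loglik += float(res.llf)
        n_params = _N_PARAMS[variant]
        return WaspFitResult(variant, coeffs_by_g0, None, beta, loglik,
                             n_params, 2.0 * n_params - 2.0 * loglik)

    cols = {"const": np.ones_like(g1), "g1": g1}
    if variant in ("2b", "2c"):
        cols["g0"] = g0
    if variant == "2c":
        cols["g0:g1"] = g0 * g1
    X = np.column_stack(list(cols.values()))
    res = _glm_fit(endog, X)
    beta = dict(zip(cols.keys(), (float(v) for v in res.params)))
    coeffs_by_g0 = {}
    for lev in levels:
        icpt = beta["const"] + beta.get("g0", 0.0) * lev
        slope = beta["g1"] + beta.get("g0:g1", 0.0) * lev
        coeffs_by_g0[lev] = WaspLogitCoeffs(icpt, slope)
    shared = WaspLogitCoeffs(beta["const"], beta["g1"]) if variant == "2a" else None
    loglik = float(res.llf)
    n_params = _N_PARAMS[variant]
    return WaspFitResult(variant, coeffs_by_g0, shared, beta, loglik,
                         n_params, 2.0 * n_params - 2.0 * loglik)


def wasp_model_table(data: pd.DataFrame, variants: Sequence[str] = VARIANTS) -> pd.DataFrame:
    """AIC comparison table over the wasp model variants (cf. fly table)."""
    rows = []
    fits: Dict[str, WaspFitResult] = {}
    for v in variants:
        try:
            fit = fit_wasp_variant(data, v)
            fits[v] = fit
            rows.append({"variant": v, "n_params": fit.n_params,
                         "loglik": fit.loglik, "aic": fit.aic, "error": ""})
        except Exception as exc:  # noqa: BLE001
            rows.append({"variant": v, "n_params": np.nan, "loglik": np.nan,
                         "aic": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table = table.sort_values(
        by=["aic", "n_params", "variant"], kind="mergesort"
    ).reset_index(drop=True)
    table.attrs["fits"] = fits
    return table


def total_count_independence(data: pd.DataFrame):
    """OLS test that total emergences per vial are independent of G1.

    Returns (F, (df_num, df_den), p) from the regression of
    wasp_count + fly_count on g1_temp; df = (1, n - 2).
    """
    if len(data) < 3:
        raise ValidationError("data", "need >= 3 records")
    g1 = data["g1_temp"].to_numpy(dtype=float)
    if np.ptp(g1) == 0:
        raise ValidationError("g1_temp", "degenerate predictor (single G1 level)")
    total = (data["wasp_count"] + data["fly_count"]).to_numpy(dtype=float)
    res = sm.OLS(total, sm.add_constant(g1)).fit()
    return float(res.fvalue), (1, int(res.df_resid)), float(res.f_pvalue)
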