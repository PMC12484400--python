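"""Linear mixed model for log time-to-extinction with Type III F tests.

The model is

    log(extinction generation) ~ autocorr * fly_tge * wasp_tge + (1 | seed)

with the three two-level treatments coded sum-to-zero (-1 / +1), so each
fixed term carries one numerator degree of freedom and -- in a balanced
grid -- the Type III Wald F for a term equals its classical ANOVA F.

Variance components are estimated by REML (statsmodels MixedLM).  The
denominator degrees of freedom use Satterthwaite's approximation:

    df_j = 2 * (c' C(theta) c)^2 / Var(c' C(theta) c)

with C(theta) = (X' V(theta)^{-1} X)^{-1}, the variance of the quadratic
form obtained by the delta method (gradient of c'Cc in the variance
components, asymptotic covariance of the components from the inverse
observed REML information).  In a balanced random-intercept design this
reproduces the exact within-subject df, n_obs - n_groups - (p - 1).
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

TERMS = [
    "autocorr",
    "fly_tge",
    "wasp_tge",
    "autocorr:fly_tge",
    "autocorr:wasp_tge",
    "fly_tge:wasp_tge",
    "autocorr:fly_tge:wasp_tge",
]


def design_matrix(results: pd.DataFrame) -> Tuple[np.ndarray, List[str]]:
    """Sum-to-zero coded design for the 2x2x2 factorial (+ intercept)."""
    a = np.where(results["rho"].to_numpy(dtype=float) > 0, 1.0, -1.0)
    f = np.where(results["fly_tge"].to_numpy(dtype=bool), 1.0, -1.0)
    w = np.where(results["wasp_tge"].to_numpy(dtype=bool), 1.0, -1.0)
    X = np.column_stack([np.ones_like(a), a, f, w, a * f, a * w, f * w, a * f * w])
    return X, ["(Intercept)"] + TERMS


def _group_indices(groups: np.ndarray) -> List[np.ndarray]:
    order: Dict = {}
    for i, g in enumerate(groups):
        order.setdefault(g, []).append(i)
    return [np.asarray(ix) for ix in order.values()]


def _gls_pieces(theta, y, X, gidx):
    """Per-group compound-symmetry algebra: V_i = se*I + sg*J."""
    sg, se = theta
    p = X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    yVy = 0.0
    logdet = 0.0
    for ix in gidx:
        Xi = X[ix]
        yi = y[ix]
        m = len(ix)
        lam = se + m * sg
        w = sg / lam
        # V_i^{-1} = (I - w * J) / se
        Xs = Xi.sum(axis=0)
        ys = yi.sum()
        XtVX += (Xi.T @ Xi - w * np.outer(Xs, Xs)) / se
        XtVy += (Xi.T @ yi - w * Xs * ys) / se
        yVy += (yi @ yi - w * ys * ys) / se
        logdet += (m - 1) * np.log(se) + np.log(lam)
    return XtVX, XtVy, yVy, logdet


def reml_neg_loglik(theta, y, X, gidx) -> float:
    sg, se = theta
    if se <= 0 or sg < 0:
        return np.inf
    XtVX, XtVy, yVy, logdet = _gls_pieces(theta, y, X, gidx)
    sign, logdet_XtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtVX, XtVy)
    quad = yVy - XtVy @ beta
    return 0.5 * (logdet + logdet_XtVX + quad)


def _fit_reml(y, X, gidx):
    """REML estimates (sigma2_group, sigma2_resid) for the random-intercept
    model, by direct optimization of the closed-form profile likelihood."""
    from scipy import optimize

    # Moment-based start: between/within decomposition of OLS residuals.
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    se0 = float(np.var(resid)) or 1e-8
    gm = np.array([resid[ix].mean() for ix in gidx])
    sg0 = max(float(np.var(gm)) - se0 / max(len(gidx[0]), 1), 1e-8)

    def obj(x):
        return reml_neg_loglik((np.exp(x[0]), np.exp(x[1])), y, X, gidx)

    best = None
    for x0 in ([np.log(sg0), np.log(se0)], [np.log(se0), np.log(se0)],
               [np.log(1e-6 * se0), np.log(se0)]):
        res = optimize.minimize(obj, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    sg, se = np.exp(best.x)
    return float(sg), float(se)


def _satterthwaite_df(theta, y, X, gidx, j: int) -> float:
    """Satterthwaite denominator df for coefficient j."""

    def c_var(th):
        XtVX, _, _, _ = _gls_pieces(th, y, X, gidx)
        return np.linalg.inv(XtVX)[j, j]

    v = c_var(theta)
    # Delta-method gradient of c'Cc in (sg, se).
    g = np.zeros(2)
    for i in range(2):
        h = max(1e-6, 1e-4 * abs(theta[i]))
        up = np.array(theta, dtype=float)
        dn = np.array(theta, dtype=float)
        up[i] += h
        dn[i] = max(dn[i] - h, 0.0 if i == 0 else 1e-12)
        g[i] = (c_var(up) - c_var(dn)) / (up[i] - dn[i])
    # Observed REML information of the variance components.
    H = np.zeros((2, 2))
    h0 = max(1e-6, 1e-4 * abs(theta[0]))
    h1 = max(1e-6, 1e-4 * abs(theta[1]))
    hs = (h0, h1)

    def f(th):
        return reml_neg_loglik(th, y, X, gidx)

    f0 = f(theta)
    for i in range(2):
        for k in range(i, 2):
            ei = np.zeros(2)
            ek = np.zeros(2)
            ei[i] = hs[i]
            ek[k] = hs[k]
            t = np.asarray(theta, dtype=float)
            if i == k:
                H[i, i] = (f(t + ei) - 2 * f0 + f(t - ei)) / hs[i] ** 2
            else:
                H[i, k] = H[k, i] = (
                    f(t + ei + ek) - f(t + ei - ek) - f(t - ei + ek) + f(t - ei - ek)
                ) / (4 * hs[i] * hs[k])
    try:
        A = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return float(len(y) - X.shape[1])
    var_v = float(g @ A @ g)
    if var_v <= 0:
        return float(len(y) - X.shape[1])
    return 2.0 * v**2 / var_v


def fit_extinction_lmm(results: pd.DataFrame, response: str = "extinction_generation",
                       group: str = "seed") -> pd.DataFrame:
    """Type III ANOVA (Satterthwaite df) of log time-to-extinction.

    Censored or failed rows are excluded (with a logged count).  Falls back
    to a fixed-effects ANOVA with a logged warning when the random-intercept
    variance collapses to (numerically) zero.
    """
    df = results
    if "censored" in df.columns and df["censored"].any():
        n = int(df["censored"].sum())
        log.warning("excluding %d censored run(s) from the mixed model", n)
        df = df[~df["censored"]]
    if "failed" in df.columns and df["failed"].any():
        df = df[~df["failed"]]
    y = np.log(df[response].to_numpy(dtype=float))
    if (df[response] <= 0).any():
        raise ValueError("non-positive extinction times; cannot take logs")
    X, names = design_matrix(df)
    groups = df[group].to_numpy()
    gidx = _group_indices(groups)
    n, p = X.shape

    if np.var(y) < 1e-24:
        rows = [{"term": t, "F": 0.0, "df_num": 1, "df_den": float(n - p), "p": 1.0}
                for t in TERMS]
        return pd.DataFrame(rows)

    sg, se = _fit_reml(y, X, gidx)

    singular = not np.isfinite(sg) or sg <= 1e-10 * se
    if singular:
        log.warning("singular random-intercept fit (sg=%.3g); falling back to OLS ANOVA", sg)
        import statsmodels.api as sm

        ols = sm.OLS(y, X).fit()
        rows = []
        for j, t in enumerate(TERMS, start=1):
            F = float(ols.tvalues[j] ** 2)
            dfd = float(ols.df_resid)
            rows.append({"term": t, "F": F, "df_num": 1, "df_den": dfd,
                         "p": float(stats.f.sf(F, 1, dfd))})
        return pd.DataFrame(rows)

    theta = (sg, se)
    XtVX, XtVy, _, _ = _gls_pieces(theta, y, X, gidx)
    C = np.linalg.inv(XtVX)
    beta = C @ XtVy
    rows = []
    for j, t in enumerate(TERMS, start=1):
        F = float(beta[j] ** 2 / C[j, j])
        dfd = _satterthwaite_df(theta, y, X, gidx, j)
        rows.append({"term": t, "F": F, "df_num": 1, "df_den": float(dfd),
                     "p": float(stats.f.sf(F, 1, dfd))})
    return pd.DataFrame(rows)
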