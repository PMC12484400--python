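"""Coupled host-parasitoid dynamics with temperature-dependent rates.

Two discrete-generation Nicholson-Bailey-style models share a logistic
host-production step

    N*_{t+1} = max(0, gamma * r(T) * N_t * (1 - N_t / K_H))

where r(T) is the fly thermal performance curve and gamma a dimensionless
failure/scaling rate.  They differ in how parasitism converts potential
hosts into next-generation wasps:

* Model A (Type II functional response):
    kills = P_t * alpha * N* / (1 + alpha * h * N*)   (truncated at N*)
    N_{t+1} = N* - kills;  P_{t+1} = kills + d
* Model B (aggregated attacks, negative-binomial escape):
    S = (1 + alpha * P_t / (k * (1 + alpha * h * N*)))**(-k)
    N_{t+1} = N* * S;  P_{t+1} = N* * (1 - S) + d

alpha = t_p * eta(T) scales the modelled wasp proportion eta into an
attack rate; h is the handling time (1/h the per-wasp kill ceiling), d a
small wasp immigration, k the spatial-aggregation parameter (k -> inf
recovers exponential random escape).

With transgenerational effects switched on, the parameters behind r and
eta depend on the previous generation's temperature through the
interpolators; otherwise the G0-blind fits (fly variant 1b, wasp variant
2a) are used.  Populations are continuous and the dynamics deterministic
given the temperature trajectory; all stochasticity is environmental.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .errors import CalibrationError, SimulationError, ValidationError
from .fly_tpc import TPCParams, _deutsch
from .interpolate import InterpolatedFlyTPC, InterpolatedWaspEta
from .wasp_glm import WaspLogitCoeffs
from scipy.special import expit


@dataclasses.dataclass
class FitBundle:
    """Fitted temperature dependences the simulator draws from."""

    fly_shared: TPCParams                  # variant 1b (no TGE)
    fly_itp: InterpolatedFlyTPC            # variant 1d nodes (fly TGE)
    wasp_shared: WaspLogitCoeffs           # variant 2a (no TGE)
    wasp_itp: InterpolatedWaspEta          # variant 2d nodes (wasp TGE)


@dataclasses.dataclass
class Modes:
    fly_tge: bool = False
    wasp_tge: bool = False


@dataclasses.dataclass
class SimParams:
    gamma: float
    t_p: float
    K_H: float = 2000.0
    h: float = 0.01
    d: float = 0.5
    k: float = 1.0
    extinction_threshold: float = 1.0

    def __post_init__(self):
        for name in ("gamma", "t_p", "K_H", "h", "k", "extinction_threshold"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(name, f"must be finite and >= 0, got {v}")
        if self.h <= 0:
            raise ValidationError("h", "handling time must be > 0")
        if self.k <= 0:
            raise ValidationError("k", "aggregation parameter must be > 0")
        if self.d < 0:
            raise ValidationError("d", "immigration must be >= 0")


@dataclasses.dataclass
class SimState:
    N: float
    P: float
    t: int = 0
    T_prev: float = 24.0


@dataclasses.dataclass
class ScenarioResult:
    model: str
    fly_tge: bool
    wasp_tge: bool
    rho: float
    seed: int
    extinction_generation: int
    censored: bool
    series: Optional[dict] = None


def growth_rate(T, T_prev, fly_tge: bool, fits: FitBundle):
    """Per-generation host growth rate r(T); vectorized over runs."""
    if fly_tge:
        topt, rmax, a = fits.fly_itp.arrays_at(T_prev)
        return _deutsch(T, topt, rmax, a, fits.fly_itp.ctmax)
    p = fits.fly_shared
    return _deutsch(T, p.topt, p.rmax, p.a, p.ctmax)


def attack_rate(T, T_prev, wasp_tge: bool, fits: FitBundle, t_p: float):
    """Attack rate alpha = t_p * eta(T); eta's coefficients may track T_prev."""
    if wasp_tge:
        icpt, slope = fits.wasp_itp.arrays_at(T_prev)
    else:
        icpt, slope = fits.wasp_shared.intercept, fits.wasp_shared.slope
    return t_p * expit(icpt + slope * np.asarray(T, dtype=float))


def _advance(N, P, r, alpha, p: SimParams, model: str):
    """One generation for vectors of states; returns (N*, N', P')."""
    nstar = np.maximum(p.gamma * r * N * (1.0 - N / p.K_H), 0.0)
    denom = 1.0 + alpha * p.h * nstar
    if model == "A":
        kills = np.minimum(P * alpha * nstar / denom, nstar)
        n1 = nstar - kills
        p1 = kills + p.d
    elif model == "B":
        surv = (1.0 + alpha * P / (p.k * denom)) ** (-p.k)
        n1 = nstar * surv
        p1 = nstar * (1.0 - surv) + p.d
    else:
        raise ValidationError("model", f"must be 'A' or 'B', got {model!r}")
    return nstar, n1, p1


def step_model_a(s: SimState, T: float, p: SimParams, modes: Modes, fits: FitBundle) -> SimState:
    """Single Model A step (Type II functional response)."""
    r = growth_rate(T, s.T_prev, modes.fly_tge, fits)
    alpha = attack_rate(T, s.T_prev, modes.wasp_tge, fits, p.t_p)
    _, n1, p1 = _advance(s.N, s.P, r, alpha, p, "A")
    return SimState(N=float(n1), P=float(p1), t=s.t + 1, T_prev=float(T))


def step_model_b(s: SimState, T: float, p: SimParams, modes: Modes, fits: FitBundle) -> SimState:
    """Single Model B step (aggregated parasitoid attacks)."""
    r = growth_rate(T, s.T_prev, modes.fly_tge, fits)
    alpha = attack_rate(T, s.T_prev, modes.wasp_tge, fits, p.t_p)
    _, n1, p1 = _advance(s.N, s.P, r, alpha, p, "B")
    return SimState(N=float(n1), P=float(p1), t=s.t + 1, T_prev=float(T))


def first_extinction_generation(N_series, threshold: float = 1.0):
    """First 1-based generation at which N falls below threshold, else None."""
    below = np.nonzero(np.asarray(N_series) < threshold)[0]
    return int(below[0]) + 1 if below.size else None


def simulate_batch(temps: np.ndarray, p: SimParams, model: str, modes: Modes,
                   fits: FitBundle, N0: float, P0: float):
    """Run many trajectories at once.

    temps has shape (n_runs, n_gen).  Returns (ext_gen, censored, N, P)
    where ext_gen is the first 1-based generation with N below the
    extinction threshold (horizon if censored) and N, P the final series
    arrays of shape (n_runs, n_gen).
    """
    temps = np.atleast_2d(np.asarray(temps, dtype=float))
    n_runs, n_gen = temps.shape
    N = np.full(n_runs, float(N0))
    P = np.full(n_runs, float(P0))
    ext = np.zeros(n_runs, dtype=int)
    Ns = np.empty((n_runs, n_gen))
    Ps = np.empty((n_runs, n_gen))
    t_prev = temps[:, 0]
    for t in range(n_gen):
        T = temps[:, t]
        r = growth_rate(T, t_prev, modes.fly_tge, fits)
        alpha = attack_rate(T, t_prev, modes.wasp_tge, fits, p.t_p)
        _, N, P = _advance(N, P, r, alpha, p, model)
        if not (np.all(np.isfinite(N)) and np.all(np.isfinite(P))):
            bad = int(np.nonzero(~(np.isfinite(N) & np.isfinite(P)))[0][0])
            raise SimulationError(
                f"non-finite state at generation {t + 1} (run {bad})",
                generation=t + 1, state=(N[bad], P[bad]),
            )
        Ns[:, t] = N
        Ps[:, t] = P
        new = (ext == 0) & (N < p.extinction_threshold)
        ext[new] = t + 1
        t_prev = T
    censored = ext == 0
    ext[censored] = n_gen
    return ext, censored, Ns, Ps


def simulate_run(trajectory, p: SimParams, model: str, modes: Modes,
                 fits: FitBundle, N0: float = 1000.0, P0: float = 10.0,
                 keep_series: bool = False) -> ScenarioResult:
    """Iterate one model over a trajectory and record time to extinction.

    Extinction is the first generation at which the host population falls
    below ``p.extinction_threshold`` (one individual by default).  If the
    host survives the whole trajectory the result is censored at the
    horizon.
    """
    temps = trajectory.temps if hasattr(trajectory, "temps") else np.asarray(trajectory, float)
    if len(temps) < 1:
        raise ValidationError("trajectory", "must contain at least one generation")
    ext, censored, Ns, Ps = simulate_batch(temps[None, :], p, model, modes, fits, N0, P0)
    series = None
    if keep_series:
        series = {"T": np.asarray(temps), "N": Ns[0], "P": Ps[0]}
    return ScenarioResult(
        model=model, fly_tge=modes.fly_tge, wasp_tge=modes.wasp_tge,
        rho=getattr(trajectory, "rho", float("nan")),
        seed=getattr(trajectory, "seed", -1),
        extinction_generation=int(ext[0]), censored=bool(censored[0]),
        series=series,
    )


def equilibrium_state(p: SimParams, fits: FitBundle, model: str = "A",
                      T: float = 24.0, modes: Optional[Modes] = None):
    """Coexistence fixed point (N, P) at constant temperature T.

    Solves the one-dimensional fixed-point condition for the host density
    (the parasitoid follows as P = N* - N + d).  When several roots exist
    the one with the highest parasitised fraction (the coexistence branch)
    is returned; with t_p = 0 this reduces to the host-only equilibrium.
    Returns None when no positive fixed point exists.

    Starting simulations here is what a burn-in is for: it removes the
    explosive transient a far-from-equilibrium start would inject into
    the tightly coupled parasitoid dynamics.
    """
    from scipy.optimize import brentq

    modes = modes or Modes(False, False)
    r = float(growth_rate(T, T, modes.fly_tge, fits))
    a = float(attack_rate(T, T, modes.wasp_tge, fits, p.t_p))
    K = p.K_H
    if r <= 0 or p.gamma <= 0:
        return None

    def nstar(N):
        return max(p.gamma * r * N * (1.0 - N / K), 0.0)

    def g(N):
        ns = nstar(N)
        if ns <= 0:
            return N
        if model == "A":
            return (ns - N) * (1.0 + a * p.h * ns) - (ns - N + p.d) * a * ns
        S = (1.0 + a * (ns - N + p.d) / (p.k * (1.0 + a * p.h * ns))) ** (-p.k)
        return N - ns * S

    grid = np.linspace(1e-6 * K, 0.999 * K, 4000)
    vals = np.array([g(N) for N in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
            try:
                roots.append(brentq(g, grid[i], grid[i + 1]))
            except ValueError:  # pragma: no cover
                continue
    cands = []
    for N in roots:
        ns = nstar(N)
        if ns > 0 and N > 0:
            cands.append((N, ns - N + p.d, (ns - N) / ns))
    if not cands:
        return None
    N, P, _ = max(cands, key=lambda c: c[2])
    return float(N), float(P)


def parasitism_fraction(temps, p: SimParams, model: str, modes: Modes,
                        fits: FitBundle, N0: float, P0: float,
                        window: int = 100) -> float:
    """Mean late-window fraction of potential hosts parasitised.

    The fraction per generation is (N* - N_{t+1}) / N*; averaged over the
    final ``window`` generations of a constant-temperature run.  If the
    host collapses below the extinction threshold the attack was too
    strong for coexistence and 1.0 is returned (overshoot sentinel).
    """
    temps = np.asarray(temps, dtype=float)
    N = float(N0)
    P = float(P0)
    t_prev = temps[0]
    fracs = []
    for t, T in enumerate(temps):
        r = growth_rate(T, t_prev, modes.fly_tge, fits)
        alpha = attack_rate(T, t_prev, modes.wasp_tge, fits, p.t_p)
        nstar, n1, p1 = _advance(N, P, r, alpha, p, model)
        fracs.append((nstar - n1) / nstar if nstar > 0 else 0.0)
        N, P = float(n1), float(p1)
        if N < p.extinction_threshold:
            return 1.0
        t_prev = T
    return float(np.mean(fracs[-window:]))


def calibrate_attack_coefficient(
    p: SimParams, fits: FitBundle, model: str = "A", T: float = 24.0,
    n_gen: int = 500, window: int = 100, band=(0.45, 0.55),
    N0: float = 1000.0, P0: float = 10.0, t_p_max: float = 1e3,
) -> float:
    """Tune t_p so that equilibrium parasitism at constant T is ~50%.

    Doubles t_p until the late-burn-in parasitised fraction reaches the
    target (a host collapse counts as overshoot), then bisects into
    ``band``, requiring persistent host dynamics at the returned value.
    Transgenerational modes are off during calibration (the pre-warming
    baseline).  Raises :class:`CalibrationError` with the achieved range
    if no persistent t_p lands in the band.
    """
    temps = np.full(n_gen, float(T))
    modes = Modes(False, False)

    def frac(tp: float) -> float:
        q = dataclasses.replace(p, t_p=tp)
        eq = equilibrium_state(q, fits, model=model, T=T, modes=modes)
        n0, p0 = eq if eq is not None else (N0, P0)
        return parasitism_fraction(temps, q, model, modes, fits, n0, p0, window)

    lo, f_lo = 0.0, frac(0.0)
    if f_lo > band[1]:
        raise CalibrationError("parasitism exceeds band at t_p = 0", achieved=f_lo)
    best = (f_lo, lo)
    hi = 1e-3
    f_hi = frac(hi)
    while f_hi < 0.5 and f_hi < 1.0:
        if f_hi > best[0]:
            best = (f_hi, hi)
        hi *= 2.0
        if hi > t_p_max:
            raise CalibrationError(
                f"no t_p <= {t_p_max} reaches 50% parasitism", achieved=best[0])
        f_hi = frac(hi)
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        f_mid = frac(mid)
        if band[0] <= f_mid <= band[1] and f_mid < 1.0:
            return mid
        if f_mid < 1.0 and f_mid > best[0]:
            best = (f_mid, mid)
        if f_mid < 0.5:
            lo = mid
        else:
            hi = mid
    if band[0] <= best[0] <= band[1]:
        return best[1]
    raise CalibrationError(
        "no persistent t_p reaches the target parasitism band",
        achieved=best[0])
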