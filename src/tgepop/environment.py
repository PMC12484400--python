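"""Warming temperature trajectories with optional AR(1) noise.

A trajectory is a burn-in of ``n_burn`` generations at a constant mean
``t_base`` followed by a linear ramp of ``warming`` degrees over ``n_ramp``
generations.  Gaussian noise with *marginal* standard deviation ``sigma``
and lag-1 autocorrelation ``rho`` is superimposed (the AR(1) innovation is
scaled by sqrt(1 - rho^2) so that trajectories with different rho have the
same stationary variance and are directly comparable).  The summed value is
capped at ``cap`` (default 30 C, the host's thermal maximum).

Shared-noise contract: the underlying standard-normal draws depend only on
``seed``, never on ``rho``, so trajectories with the same seed but
different autocorrelation are deterministic transformations of the same
noise sequence -- this is what makes paired scenario comparisons possible.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import lfilter

from .errors import ValidationError


@dataclasses.dataclass
class Trajectory:
    temps: np.ndarray
    rho: float
    sigma: float
    t_base: float
    warming: float
    n_burn: int
    n_ramp: int
    cap: float
    seed: int

    @property
    def n_gen(self) -> int:
        return len(self.temps)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"generation": np.arange(1, self.n_gen + 1),
                             "temperature": self.temps})


def ramp_mean(t_base: float, warming: float, n_burn: int, n_ramp: int) -> np.ndarray:
    """Deterministic mean series: constant burn-in then linear rise."""
    t = np.arange(n_burn + n_ramp)
    m = np.full(n_burn + n_ramp, float(t_base))
    ramp = t >= n_burn
    m[ramp] = t_base + warming * (t[ramp] - n_burn + 1) / n_ramp
    return m


def ar1_noise(n: int, rho: float, sigma: float, seed: int) -> np.ndarray:
    """Stationary AR(1) noise, marginal SD sigma, from seed-only z draws."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    u = np.sqrt(1.0 - rho**2) * sigma * z
    u[0] = sigma * z[0]  # start at the stationary marginal distribution
    return lfilter([1.0], [1.0, -rho], u)


def make_trajectory(
    rho: float = 0.0,
    sigma: float = 1.0,
    t_base: float = 24.0,
    warming: float = 5.0,
    n_burn: int = 500,
    n_ramp: int = 2000,
    cap: float = 30.0,
    seed: int = 0,
) -> Trajectory:
    """Build one temperature trajectory (burn-in + ramp + AR(1) noise + cap)."""
    for name, val in (("rho", rho), ("sigma", sigma), ("t_base", t_base),
                      ("warming", warming), ("cap", cap)):
        if not np.isfinite(val):
            raise ValidationError(name, f"must be finite, got {val}")
    if not 0.0 <= rho < 1.0:
        raise ValidationError("rho", f"must lie in [0, 1), got {rho}")
    if sigma < 0:
        raise ValidationError("sigma", f"must be >= 0, got {sigma}")
    if n_burn < 0 or n_ramp < 1:
        raise ValidationError("n_ramp", "need n_burn >= 0 and n_ramp >= 1")
    n = n_burn + n_ramp
    m = ramp_mean(t_base, warming, n_burn, n_ramp)
    eps = ar1_noise(n, rho, sigma, seed) if sigma > 0 else np.zeros(n)
    temps = np.minimum(m + eps, cap)
    return Trajectory(temps=temps, rho=rho, sigma=sigma, t_base=t_base,
                      warming=warming, n_burn=n_burn, n_ramp=n_ramp,
                      cap=cap, seed=seed)
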