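"""Transgenerational interpolation of fitted parameters.

Inside the simulator the previous generation's temperature T_prev is
continuous, while the experiments estimated parameters only at the three
parental levels (19, 23, 27 C).  Two schemes bridge the gap:

* fly TPC parameters (Topt, Rmax, a): piecewise-linear through the three
  nodes, extrapolated beyond [19, 27] with the slope of the nearest
  segment; interpolated Rmax is floored at 0.1 to keep the growth rate
  non-negative, and a is floored at 1e-3 for numerical safety.
* wasp logit coefficients (intercept, slope): the unique parabola through
  the three nodes, used for extrapolation as well.  Interpolating on the
  coefficient (logit) scale keeps the predicted proportion inside (0, 1).

With identical node values both schemes collapse to constants, i.e. the
transgenerational effect is switched off implicitly.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .fly_tpc import A_FLOOR, FlyFitResult, TPCParams
from .wasp_glm import WaspFitResult, WaspLogitCoeffs

RMAX_FLOOR = 0.1


def _piecewise_linear(x, xs, ys):
    """Linear interpolation through nodes with edge-slope extrapolation."""
    x = np.asarray(x, dtype=float)
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    out = np.interp(x, xs, ys)
    s_lo = (ys[1] - ys[0]) / (xs[1] - xs[0])
    s_hi = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    out = np.where(x < xs[0], ys[0] + s_lo * (x - xs[0]), out)
    out = np.where(x > xs[-1], ys[-1] + s_hi * (x - xs[-1]), out)
    return out


@dataclasses.dataclass
class InterpolatedFlyTPC:
    node_temps: Sequence[float]
    node_params: Sequence[TPCParams]
    rmax_floor: float = RMAX_FLOOR

    def __post_init__(self):
        t = np.asarray(self.node_temps, dtype=float)
        if len(t) != 3 or not np.all(np.diff(t) > 0):
            raise ValidationError("node_temps", "need exactly 3 strictly increasing nodes")
        if len(self.node_params) != 3:
            raise ValidationError("node_params", "need exactly 3 parameter sets")
        self._t = t
        self._topt = np.array([p.topt for p in self.node_params])
        self._rmax = np.array([p.rmax for p in self.node_params])
        self._a = np.array([p.a for p in self.node_params])
        self.ctmax = self.node_params[0].ctmax
        self.theta = self.node_params[0].theta

    @classmethod
    def from_fit(cls, fit: FlyFitResult) -> "InterpolatedFlyTPC":
        levels = sorted(fit.params.by_g0)
        params = [dataclasses.replace(fit.params.by_g0[g], theta=fit.params.theta)
                  for g in levels]
        return cls(node_temps=levels, node_params=params)

    def arrays_at(self, t_prev):
        """Vectorized (topt, rmax, a) at previous-generation temperature(s)."""
        topt = _piecewise_linear(t_prev, self._t, self._topt)
        rmax = np.maximum(_piecewise_linear(t_prev, self._t, self._rmax), self.rmax_floor)
        a = np.maximum(_piecewise_linear(t_prev, self._t, self._a), A_FLOOR)
        return topt, rmax, a

    def __call__(self, t_prev: float) -> TPCParams:
        return self.fly_params_at(t_prev)

    def fly_params_at(self, t_prev: float) -> TPCParams:
        topt, rmax, a = self.arrays_at(float(t_prev))
        return TPCParams(topt=float(min(topt, self.ctmax - 1e-9)), rmax=float(rmax),
                         a=float(a), ctmax=self.ctmax, theta=self.theta)


@dataclasses.dataclass
class InterpolatedWaspEta:
    node_temps: Sequence[float]
    node_coeffs: Sequence[WaspLogitCoeffs]

    def __post_init__(self):
        t = np.asarray(self.node_temps, dtype=float)
        if len(t) != 3 or not np.all(np.diff(t) > 0):
            raise ValidationError("node_temps", "need exactly 3 strictly increasing nodes")
        if len(self.node_coeffs) != 3:
            raise ValidationError("node_coeffs", "need exactly 3 coefficient sets")
        self._t = t
        # Exact interpolating parabola for each coefficient.
        self._icpt_poly = np.polyfit(t, [c.intercept for c in self.node_coeffs], 2)
        self._slope_poly = np.polyfit(t, [c.slope for c in self.node_coeffs], 2)

    @classmethod
    def from_fit(cls, fit: WaspFitResult) -> "InterpolatedWaspEta":
        levels = sorted(fit.coeffs_by_g0)
        return cls(node_temps=levels, node_coeffs=[fit.coeffs_by_g0[g] for g in levels])

    def arrays_at(self, t_prev):
        t_prev = np.asarray(t_prev, dtype=float)
        return np.polyval(self._icpt_poly, t_prev), np.polyval(self._slope_poly, t_prev)

    def __call__(self, t_prev: float) -> WaspLogitCoeffs:
        return self.wasp_coeffs_at(t_prev)

    def wasp_coeffs_at(self, t_prev: float) -> WaspLogitCoeffs:
        icpt, slope = self.arrays_at(float(t_prev))
        return WaspLogitCoeffs(float(icpt), float(slope))


def fly_params_at(t_prev: float, itp: InterpolatedFlyTPC) -> TPCParams:
    """Functional alias for :meth:`InterpolatedFlyTPC.fly_params_at`."""
    return itp.fly_params_at(t_prev)


def wasp_coeffs_at(t_prev: float, itp: InterpolatedWaspEta) -> WaspLogitCoeffs:
    """Functional alias for :meth:`InterpolatedWaspEta.wasp_coeffs_at`."""
    return itp.wasp_coeffs_at(t_prev)
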