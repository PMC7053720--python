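"""Effect-site kinetics and the Hill-law dopaminergic input.

Plasma concentration does not act on the basal ganglia instantaneously.
Three stages stand between plasma and the network drive:

1. an *effect compartment* with unit steady-state gain,
   ``c3' = ke3 (c1(t) - c3)``, ``c3(0) = 0`` (12-hour washout), whose rate
   constant ``ke3`` (1/min) controls how fast the brain tracks plasma;
2. a *pure delay* ``T`` (minutes): ``c3delay(t) = c3(t - T)``, zero before
   the delayed signal exists;
3. the *Hill law* mapping delayed effect-site concentration to the
   dimensionless dopaminergic input

   .. math:: D(t) = D_0 + D_{max} \\frac{c^{N_D}}{D_{c50}^{N_D} + c^{N_D}}

   where ``D0`` is the pre-dose dopaminergic tone, ``Dmax`` the maximal
   drug-induced increment, ``Dc50`` the half-effect concentration and
   ``ND`` the Hill coefficient (steepness: large ``ND`` makes the response
   all-or-nothing).

The classic link-compartment form in stage 1 withdraws no mass from plasma
and has unit gain; any true plasma-to-brain gain is absorbed into the
fitted ``Dc50``, which is why the effect-site volume never appears.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import lfilter
from scipy.special import expit

from .errors import InputError, InvalidParameterError
from .series import SampledSeries

__all__ = [
    "PDParameters",
    "effect_compartment",
    "apply_delay",
    "dopaminergic_input",
    "dopaminergic_response",
]

#: Internal dense grid step (minutes) for effect-site integration.
INTERNAL_GRID_MIN = 1.0


@dataclass(frozen=True)
class PDParameters:
    """The six estimated pharmacodynamic quantities (see module docstring)."""

    ke3: float   # 1/min, removal from the effect compartment
    T: float     # min, pure delay of the central effect
    D0: float    # dimensionless basal dopaminergic input
    Dmax: float  # dimensionless maximal drug-induced increment
    Dc50: float  # mg/l, half-effect effect-site concentration
    ND: float    # Hill coefficient

    def __post_init__(self) -> None:
        for name in ("ke3", "T", "D0", "Dmax", "Dc50", "ND"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")
        for name in ("ke3", "Dmax", "Dc50", "ND"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.T < 0:
            raise InvalidParameterError("delay T must be non-negative")
        if self.D0 < 0:
            raise InvalidParameterError("D0 must be non-negative")


def _filter_first_order(u: np.ndarray, ke3: float, h: float) -> np.ndarray:
    """Exact solution of ``y' = ke3 (u - y)`` on a uniform grid, ``y[0] = 0``,
    for piecewise-linear input ``u``.

    The update ``y[n+1] = alpha y[n] + beta u[n] + gamma u[n+1]`` with
    ``alpha = exp(-ke3 h)`` is an IIR filter; coefficients follow from
    integrating the linear interpolant exactly.
    """
    kh = ke3 * h
    alpha = np.exp(-kh)
    one_m_alpha = -np.expm1(-kh)
    # y(h) = y0 a + u0 (1-a) + s (h - (1-a)/k), s = (u1-u0)/h
    #      = y0 a + u0 [(1-a) - (1 - (1-a)/kh)] + u1 [1 - (1-a)/kh]
    if kh < 1e-4:
        # series for the u[n+1] weight; the direct form cancels
        # catastrophically and can turn slightly negative
        g = kh / 2.0 - kh * kh / 6.0
    else:
        g = 1.0 - one_m_alpha / kh   # weight of u[n+1]
    beta = one_m_alpha - g           # weight of u[n]
    # initial condition pins y[0] = 0 exactly (post-washout effect site)
    y, _ = lfilter([g, beta], [1.0, -alpha], u, zi=np.array([-g * u[0]]))
    return y


def effect_compartment(
    c1: SampledSeries, ke3: float, grid_min: float = INTERNAL_GRID_MIN
) -> SampledSeries:
    """Effect-site concentration ``c3`` driven by plasma ``c1``.

    ``c1`` is linearly interpolated to a dense internal grid, the link ODE is
    integrated exactly for that piecewise-linear input, and the result is
    returned on the original time grid of ``c1``.
    """
    if ke3 <= 0:
        raise InvalidParameterError("ke3 must be strictly positive")
    grid = np.arange(int(np.ceil(c1.times[-1] / grid_min)) + 1) * grid_min
    if grid.size < 2:
        grid = np.array([0.0, grid_min])
    u = c1.interp(grid, left=c1.values[0], right=c1.values[-1])
    y = _filter_first_order(u, ke3, grid_min)
    return SampledSeries(c1.times, np.interp(c1.times, grid, y))


def apply_delay(c3: SampledSeries, T: float) -> SampledSeries:
    """Pure delay: ``c3delay(t) = c3(t - T)``, 0 for ``t < T`` (washout).

    Off-grid values come from a monotone cubic (PCHIP) interpolant of the
    series rather than linear interpolation: the estimator minimizes over
    ``T``, and a C1 interpolant keeps the cost surface free of kinks at
    every grid knot (linear interpolation leaves the optimizer a field of
    micro-minima).  For fewer than three samples it falls back to linear.
    """
    if T < 0:
        raise InvalidParameterError("delay T must be non-negative")
    t_shift = c3.times - T
    if len(c3) >= 3:
        interp = PchipInterpolator(c3.times, c3.values, extrapolate=False)
        vals = interp(np.clip(t_shift, c3.times[0], c3.times[-1]))
    else:
        vals = np.interp(t_shift, c3.times, c3.values)
    shifted = np.where(t_shift < c3.times[0], 0.0, vals)
    return c3.with_values(shifted)


def dopaminergic_input(c3delay: SampledSeries, pd: PDParameters) -> SampledSeries:
    """Hill-law dopaminergic input ``D(t)`` from delayed effect-site levels."""
    c = np.asarray(c3delay.values, dtype=float)
    if np.any(c < -1e-9):
        raise InputError("effect-site concentration must be non-negative")
    c = np.clip(c, 0.0, None)  # round-off from the exact solvers
    hill = hill_response(c, pd)
    return c3delay.with_values(hill)


def hill_response(c: np.ndarray, pd: PDParameters) -> np.ndarray:
    """Vectorized Hill law ``D0 + Dmax c^ND / (Dc50^ND + c^ND)``.

    Evaluated as a logistic in log-concentration, which cannot overflow
    even for extreme Hill coefficients.
    """
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        logratio = np.where(c > 0, np.log(c) - np.log(pd.Dc50), -np.inf)
    return pd.D0 + pd.Dmax * expit(pd.ND * logratio)


def dopaminergic_response(
    c1_dense: SampledSeries, pd: PDParameters, grid_min: float = INTERNAL_GRID_MIN
) -> SampledSeries:
    """Full plasma-to-D pipeline on a dense grid.

    Composes effect compartment, pure delay and Hill law; intended for the
    estimator, which evaluates it thousands of times, so every stage is a
    vectorized O(n) pass.
    """
    c3 = effect_compartment(c1_dense, pd.ke3, grid_min=grid_min)
    c3d = apply_delay(c3, pd.T)
    return dopaminergic_input(c3d, pd)
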