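"""Closed-form moments of the drift-OU axonal growth model.

All expressions follow from the linear Langevin equation
``dV/dt = a0 - gamma1 V + Gamma(t)`` with Gaussian white noise of strength
``sigma2`` and a fixed initial velocity ``V0``:

* mean velocity        <V(t)>   = a0/g + (V0 - a0/g) e^{-g t}
* velocity correlation <V(t1) V(t2)>  (four terms: drift^2, transient^2,
  cross, and the stationary OU noise term)
* mean position        <x(t)>  (integral of the mean velocity)
* mean squared length  <L^2(t)> = <(x - x0)^2> about the drift ramp
  (the variance of the position plus the squared transient of the mean),
  and the literal second moment of the displacement including the drift
* diffusion (motility) coefficient  D = sigma2 / (2 gamma1^2)

with ``g = gamma1``.  Everything is vectorised over the time argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import GrowthParams, ValidationError

__all__ = [
    "mean_velocity",
    "velocity_correlation",
    "mean_squared_velocity",
    "mean_position",
    "mean_squared_length",
    "mean_squared_length_diffusion_form",
    "mean_squared_displacement_full",
    "asymptotic_msl",
    "diffusion_coefficient",
    "characteristic_time",
    "linear_regime_check",
    "LinearRegime",
]


def _check_time(t, name: str = "t"):
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} must be finite")
    if np.any(arr < 0):
        raise ValidationError(f"{name} must be >= 0")
    return arr


def _maybe_scalar(arr, t):
    return float(arr) if np.isscalar(t) or np.ndim(t) == 0 else arr


def mean_velocity(params: GrowthParams, t):
    """Ensemble mean velocity ``<V(t)>`` in um/hr.

    Relaxes exponentially from ``V0`` to the terminal drift velocity
    ``a0/gamma1`` with rate ``gamma1``.
    """
    t = _check_time(t)
    vd = params.drift_velocity
    out = vd + (params.v0_mean - vd) * np.exp(-params.gamma1 * t)
    return _maybe_scalar(out, t)


def velocity_correlation(params: GrowthParams, t1, t2):
    """Two-time velocity correlation ``<V(t1) V(t2)>`` in um^2/hr^2.

    Symmetric in its time arguments; at ``t1 == t2`` it reduces to the
    mean squared velocity.
    """
    t1 = _check_time(t1, "t1")
    t2 = _check_time(t2, "t2")
    g = params.gamma1
    vd = params.drift_velocity
    dv = params.v0_mean - vd
    tsum = t1 + t2
    tdiff = np.abs(t1 - t2)
    out = (
        vd**2
        + dv**2 * np.exp(-g * tsum)
        + vd * dv * (np.exp(-g * t1) + np.exp(-g * t2))
        + params.sigma2 / (2.0 * g) * (np.exp(-g * tdiff) - np.exp(-g * tsum))
    )
    if np.ndim(t1) == 0 and np.ndim(t2) == 0:
        return float(out)
    return out


def mean_squared_velocity(params: GrowthParams, t):
    """Ensemble mean squared velocity ``<V^2(t)>`` in um^2/hr^2."""
    t = _check_time(t)
    g = params.gamma1
    vd = params.drift_velocity
    dv = params.v0_mean - vd
    e = np.exp(-g * t)
    out = vd**2 + dv**2 * e**2 + 2.0 * vd * dv * e + params.sigma2 / (2.0 * g) * (1.0 - e**2)
    return _maybe_scalar(out, t)


def mean_position(params: GrowthParams, t):
    """Mean growth-cone displacement ``<x(t)>`` along the pattern, um."""
    t = _check_time(t)
    g = params.gamma1
    vd = params.drift_velocity
    dv = params.v0_mean - vd
    # (a0/g) t + dv (1 - e^{-g t})/g, written with expm1 for small g*t
    out = vd * t - dv * np.expm1(-g * t) / g
    return _maybe_scalar(out, t)


def _msl_core(x):
    """Stable evaluation of f(x) = x + (e^{-x} - 1) - (e^{-x} - 1)^2 / 2.

    ``Var[x(t)] = sigma2 / gamma1^3 * f(gamma1 t)``; for small x the three
    terms cancel to x^3/3, so a short series is used below x = 1e-3.
    """
    x = np.asarray(x, dtype=float)
    em = np.expm1(-x)
    direct = x + em - 0.5 * em * em
    series = x**3 / 3.0 - x**4 / 4.0 + 7.0 * x**5 / 60.0
    return np.where(x < 1e-3, series, direct)


def mean_squared_length(params: GrowthParams, t):
    """Axonal mean squared length ``<L^2(t)>`` in um^2.

    This is the printed drift-free form: position variance plus the squared
    transient of the mean about the drift ramp ``(a0/gamma1) t``,

        <L^2> = sigma2/g^2 t + sigma2/(2 g^3) (4 e^{-gt} - e^{-2gt} - 3)
                + (V0 - a0/g)^2 (e^{-gt} - 1)^2 / g^2.

    The literal second moment of the displacement, which keeps the drift
    terms, is :func:`mean_squared_displacement_full`.
    """
    t = _check_time(t)
    g = params.gamma1
    dv = params.v0_mean - params.drift_velocity
    x = g * t
    em = np.expm1(-x)
    out = params.sigma2 / g**3 * _msl_core(x) + dv**2 * em**2 / g**2
    return _maybe_scalar(out, t)


def mean_squared_length_diffusion_form(params: GrowthParams, t):
    """``<L^2(t)>`` rewritten through the diffusion coefficient.

    Algebraically identical to :func:`mean_squared_length`:
    ``2 D t + (D/g) (4 e^{-gt} - e^{-2gt} - 3) + transient`` with
    ``D = sigma2/(2 g^2)``; shares the stabilised core so the identity
    holds to rounding error at all times.
    """
    t = _check_time(t)
    g = params.gamma1
    D = diffusion_coefficient(params)
    dv = params.v0_mean - params.drift_velocity
    x = g * t
    em = np.expm1(-x)
    out = 2.0 * D / g * _msl_core(x) + dv**2 * em**2 / g**2
    return _maybe_scalar(out, t)


def mean_squared_displacement_full(params: GrowthParams, t):
    """Literal second moment ``<(x(t) - x0)^2>`` in um^2, drift included.

    Equals :func:`mean_squared_length` plus ``[(a0/g) t]^2`` plus the
    drift-transient cross term.
    """
    t = _check_time(t)
    g = params.gamma1
    vd = params.drift_velocity
    dv = params.v0_mean - vd
    em = np.expm1(-g * t)
    out = (
        np.asarray(mean_squared_length(params, t))
        + (vd * t) ** 2
        + 2.0 * vd * t * dv * (-em) / g
    )
    return _maybe_scalar(out, t)


def asymptotic_msl(params: GrowthParams, t):
    """Large-time linear asymptote of ``<L^2(t)>``: constant + 2 D t."""
    t = _check_time(t)
    g = params.gamma1
    dv = params.v0_mean - params.drift_velocity
    out = dv**2 / g**2 + params.sigma2 / g**2 * t
    return _maybe_scalar(out, t)


def diffusion_coefficient(params: GrowthParams) -> float:
    """Growth-cone diffusion (motility) coefficient, um^2/hr.

    Time integral of the centred stationary velocity autocorrelation,
    ``D = sigma2 / (2 gamma1^2)``.  Conventional cell-motility
    terminology; not a thermal-equilibrium quantity.
    """
    return params.sigma2 / (2.0 * params.gamma1**2)


def characteristic_time(params: GrowthParams) -> float:
    """Velocity relaxation time ``tau = 1/gamma1`` in hr."""
    return 1.0 / params.gamma1


@dataclass(frozen=True)
class LinearRegime:
    """Result of the quasi-linear damping check ``gamma2 V^2 << gamma1 V``."""

    ratio: float        # gamma1/gamma2, um/hr (inf when gamma2 == 0)
    satisfied: bool
    margin: float


def linear_regime_check(v: float, gamma1: float, gamma2: float, margin: float = 0.3) -> LinearRegime:
    """Check whether quadratic damping is negligible at velocity ``v``.

    The quadratic term is negligible when ``v`` is well below
    ``gamma1/gamma2``; "well below" is ``v < margin * ratio`` with a
    configurable margin (default 0.3).
    """
    for name, value in (("v", v), ("gamma1", gamma1), ("gamma2", gamma2), ("margin", margin)):
        if not math.isfinite(value):
            raise ValidationError(f"{name} must be finite")
    if gamma1 <= 0:
        raise ValidationError("gamma1 must be > 0")
    if gamma2 < 0:
        raise ValidationError("gamma2 must be >= 0")
    if gamma2 == 0.0:
        return LinearRegime(ratio=math.inf, satisfied=True, margin=margin)
    ratio = gamma1 / gamma2
    return LinearRegime(ratio=ratio, satisfied=bool(abs(v) < margin * ratio), margin=margin)
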