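"""Stochastic simulation of growth-cone dynamics.

Two integrators are provided for the reduced 1D model:

``exact``
    Samples the joint Gaussian transition of (velocity, position) for the
    drift-OU pair over each step.  The one-step distribution matches the
    continuous-time process exactly, so the step size only sets the output
    grid, never the accuracy.

``euler``
    Euler-Maruyama with the standard Wiener-increment convention
    ``V' = V + (a0 - gamma1 V) dt + sqrt(sigma2 dt) z`` and trapezoidal
    position accumulation; kept for convergence checks.

The full planar model (nonlinear damping + aligning torque) is integrated
by Euler-Maruyama only.

Random streams: one master seed; each track draws from its own
deterministic substream ``SeedSequence([seed, track_index])`` so that
changing ``n_tracks`` never reshuffles earlier tracks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .params import FullModelParams2D, GrowthParams, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "Path1D",
    "Path2D",
    "SimResult1D",
    "SimResult2D",
    "ou_exact_step",
    "simulate_1d",
    "simulate_2d",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings shared by the 1D and 2D integrators."""

    dt: float                       # step interval, hr
    duration: float                 # total simulated time, hr
    n_tracks: int
    seed: int = 0
    init_velocity_mean: float = 0.9     # um/hr
    init_velocity_sd: float = 1.0       # um/hr; 0 pins v(0) at the mean
    scheme: str = "exact"               # "exact" | "euler"

    def __post_init__(self):
        if not (self.dt > 0 and math.isfinite(self.dt)):
            raise ValidationError(f"dt must be > 0, got {self.dt}")
        if self.duration < self.dt:
            raise ValidationError("duration must be >= dt")
        if self.n_tracks < 1:
            raise ValidationError("n_tracks must be >= 1")
        if self.init_velocity_sd < 0:
            raise ValidationError("init_velocity_sd must be >= 0")
        if self.scheme not in ("exact", "euler"):
            raise ValidationError(f"unknown scheme {self.scheme!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def times(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt


@dataclass(frozen=True)
class Path1D:
    """A single 1D growth-cone path on a regular time grid."""

    times: np.ndarray      # hr, strictly increasing from 0
    velocity: np.ndarray   # um/hr
    position: np.ndarray   # um, along the pattern axis


@dataclass(frozen=True)
class Path2D:
    """A single planar path: speed, heading angle, and position."""

    times: np.ndarray
    speed: np.ndarray      # um/hr, >= 0 after the low-speed guard
    theta: np.ndarray      # radians in [0, 2pi), measured from the y axis
    x: np.ndarray          # um
    y: np.ndarray          # um


class _PathCollection:
    def __len__(self) -> int:
        return self._n

    def __iter__(self):
        return (self[i] for i in range(len(self)))


@dataclass
class SimResult1D(_PathCollection):
    """Ensemble of 1D paths; arrays are (n_tracks, n_times)."""

    times: np.ndarray
    velocity: np.ndarray
    position: np.ndarray

    def __post_init__(self):
        self._n = self.velocity.shape[0]

    def __getitem__(self, i: int) -> Path1D:
        return Path1D(self.times, self.velocity[i], self.position[i])


@dataclass
class SimResult2D(_PathCollection):
    """Ensemble of planar paths plus the low-speed-floor hit count."""

    times: np.ndarray
    speed: np.ndarray
    theta: np.ndarray
    x: np.ndarray
    y: np.ndarray
    floor_hits: int = 0
    v_floor: float = 0.1

    def __post_init__(self):
        self._n = self.speed.shape[0]

    def __getitem__(self, i: int) -> Path2D:
        return Path2D(self.times, self.speed[i], self.theta[i], self.x[i], self.y[i])


def _ou_transition(params: GrowthParams, dt: float):
    """Moments of the exact (velocity, position-increment) transition.

    For the OU velocity with relaxation rate g and noise strength s2,
    conditional on V(t)=v:

        V(t+dt)  ~ N(mu + (v-mu) E,           s2 (1-E^2)/(2g))
        x incr.  ~ N(mu dt + (v-mu)(1-E)/g,   s2 (dt - 2(1-E)/g + (1-E^2)/(2g)) / g^2)
        Cov(incr, V') = s2 (1-E)^2 / (2 g^2),   E = e^{-g dt}.
    """
    g = params.gamma1
    s2 = params.sigma2
    E = math.exp(-g * dt)
    var_v = s2 * (1.0 - E * E) / (2.0 * g)
    var_x = s2 / g**2 * (dt - 2.0 * (1.0 - E) / g + (1.0 - E * E) / (2.0 * g))
    cov = s2 * (1.0 - E) ** 2 / (2.0 * g**2)
    return E, var_v, var_x, cov


def ou_exact_step(v, dt: float, params: GrowthParams, z):
    """One exact transition of the drift-OU velocity.

    ``a0/g + (v - a0/g) e^{-g dt} + sqrt(sigma2 (1 - e^{-2 g dt})/(2g)) z``
    with ``z`` a standard normal deviate.  Vectorised over ``v``/``z``.
    """
    if not (dt > 0 and math.isfinite(dt)):
        raise ValidationError(f"dt must be > 0, got {dt}")
    E, var_v, _, _ = _ou_transition(params, dt)
    mu = params.drift_velocity
    return mu + (np.asarray(v, dtype=float) - mu) * E + math.sqrt(var_v) * np.asarray(z, dtype=float)


def _track_normals(seed: int, n_tracks: int, shape) -> np.ndarray:
    """Per-track standard normals from deterministic substreams."""
    out = np.empty((n_tracks,) + shape)
    for k in range(n_tracks):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), k]))
        out[k] = rng.standard_normal(shape)
    return out


def simulate_1d(params: GrowthParams, cfg: SimConfig) -> SimResult1D:
    """Simulate an ensemble of 1D growth-cone paths.

    Initial velocities are drawn ``N(init_velocity_mean,
    init_velocity_sd^2)`` (negative values, i.e. retraction, are allowed);
    initial positions are 0.
    """
    n, m = cfg.n_tracks, cfg.n_steps
    times = cfg.times()
    # draws: [0] initial velocity, then 2 per step (velocity & position noise)
    z = _track_normals(cfg.seed, n, (1 + 2 * m,))
    v = np.empty((n, m + 1))
    x = np.zeros((n, m + 1))
    v[:, 0] = cfg.init_velocity_mean + cfg.init_velocity_sd * z[:, 0]

    mu = params.drift_velocity
    if cfg.scheme == "exact":
        E, var_v, var_x, cov = _ou_transition(params, cfg.dt)
        sd_x = math.sqrt(var_x)
        # conditional decomposition: draw the position increment first,
        # then the velocity given the increment
        if var_x > 0 and var_v > 0:
            rho = cov / math.sqrt(var_x * var_v)
        else:
            rho = 0.0
        sd_v = math.sqrt(var_v)
        sd_v_given = sd_v * math.sqrt(max(0.0, 1.0 - rho * rho))
        for k in range(m):
            z1 = z[:, 1 + 2 * k]
            z2 = z[:, 2 + 2 * k]
            dev = v[:, k] - mu
            dx = mu * cfg.dt + dev * (1.0 - E) / params.gamma1 + sd_x * z1
            v[:, k + 1] = mu + dev * E + sd_v * rho * z1 + sd_v_given * z2
            x[:, k + 1] = x[:, k] + dx
    else:
        if params.gamma1 * cfg.dt >= 0.1:
            logger.warning(
                "Euler-Maruyama with gamma1*dt = %.3g >= 0.1: expect discretization bias",
                params.gamma1 * cfg.dt,
            )
        sd = math.sqrt(params.sigma2 * cfg.dt)
        for k in range(m):
            v[:, k + 1] = v[:, k] + (params.a0 - params.gamma1 * v[:, k]) * cfg.dt + sd * z[:, 1 + 2 * k]
            x[:, k + 1] = x[:, k] + 0.5 * (v[:, k] + v[:, k + 1]) * cfg.dt
    return SimResult1D(times=times, velocity=v, position=x)


def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    return np.mod(theta, 2.0 * math.pi)


def simulate_2d(
    params: FullModelParams2D,
    cfg: SimConfig,
    theta0_dist: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    v_floor: float = 0.1,
    strict_literal: bool = False,
) -> SimResult2D:
    """Euler-Maruyama integration of the full planar model.

    Speed follows ``dV = (a0 |sin th| - g1 V - g2 V^2) dt + sqrt(s2_par dt) z``.
    The heading evolves by the circular-motion relation ``dtheta =
    a_perp dt / max(V, v_floor)``; by default the torque magnitude
    ``|a1 cos theta|`` is directed toward the nearer of the two pattern
    directions (theta = pi/2 or 3pi/2), reflecting the +/-x symmetry of
    the parallel equation.  ``strict_literal=True`` instead applies the
    signed rule ``dtheta = (a1 cos theta dt + noise)/V``, under which only
    theta = pi/2 is an attractor.

    ``theta0_dist(rng, n)`` supplies initial headings (default: uniform on
    [0, 2pi)).  Speed is kept non-negative; steps where the speed floor
    was applied are counted in ``floor_hits``.
    """
    if params.gamma1 * cfg.dt >= 0.1:
        logger.warning(
            "2D Euler-Maruyama with gamma1*dt = %.3g >= 0.1: reduce dt",
            params.gamma1 * cfg.dt,
        )
    n, m = cfg.n_tracks, cfg.n_steps
    times = cfg.times()
    # draws: initial speed, initial heading uses its own rng stream below,
    # then per step: parallel noise, perpendicular noise
    z = _track_normals(cfg.seed, n, (1 + 2 * m,))
    rng0 = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 2**20]))
    if theta0_dist is None:
        theta = rng0.uniform(0.0, 2.0 * math.pi, size=n)
    else:
        theta = np.asarray(theta0_dist(rng0, n), dtype=float)
        if theta.shape != (n,):
            raise ValidationError("theta0_dist must return n_tracks angles")
    theta = _wrap_angle(theta)

    speed = np.empty((n, m + 1))
    th = np.empty((n, m + 1))
    x = np.zeros((n, m + 1))
    y = np.zeros((n, m + 1))
    speed[:, 0] = np.clip(cfg.init_velocity_mean + cfg.init_velocity_sd * z[:, 0], 0.0, None)
    th[:, 0] = theta

    sd_par = math.sqrt(params.sigma2_par * cfg.dt)
    sd_perp = math.sqrt(params.sigma2_perp * cfg.dt)
    floor_hits = 0
    for k in range(m):
        vk = speed[:, k]
        tk = th[:, k]
        a_par = params.a0 * np.abs(np.sin(tk)) - params.gamma1 * vk - params.gamma2 * vk**2
        v_new = vk + a_par * cfg.dt + sd_par * z[:, 1 + 2 * k]
        v_new = np.clip(v_new, 0.0, None)
        v_eff = np.maximum(vk, v_floor)
        floor_hits += int(np.count_nonzero(vk < v_floor))
        perp_noise = sd_perp * z[:, 2 + 2 * k]
        if strict_literal:
            dth = (params.a1 * np.cos(tk) * cfg.dt + perp_noise) / v_eff
        else:
            # steer toward the nearer pattern direction (pi/2 or 3pi/2)
            target = np.where(tk < math.pi, 0.5 * math.pi, 1.5 * math.pi)
            direction = np.sign(target - tk)
            direction = np.where(direction == 0, 1.0, direction)
            dth = (direction * np.abs(params.a1 * np.cos(tk)) * cfg.dt + perp_noise) / v_eff
        th[:, k + 1] = _wrap_angle(tk + dth)
        speed[:, k + 1] = v_new
        x[:, k + 1] = x[:, k] + vk * np.sin(tk) * cfg.dt
        y[:, k + 1] = y[:, k] + vk * np.cos(tk) * cfg.dt
    if floor_hits:
        logger.info("low-speed floor (v_floor=%.3g um/hr) applied at %d track-steps", v_floor, floor_hits)
    return SimResult2D(times=times, speed=speed, theta=th, x=x, y=y, floor_hits=floor_hits, v_floor=v_floor)
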