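"""Weighted least-squares estimation of the growth-model parameters.

The drift acceleration ``a0``, damping rate ``gamma1`` and noise strength
``sigma2`` are estimated from the ensemble mean-velocity and mean-squared
-velocity series, with the initial mean velocity ``V0`` fixed from the
t = 0 distribution.  Two weighting schemes are available:

``"sem"``
    Independent diagonal weights 1/SEM^2 per point, applied to each
    series separately.

``"gls"`` (default when per-cone samples are available)
    Per-time-point generalised least squares: the 2-vector of residuals
    (mean, mean-square) at each time is whitened by the Cholesky factor
    of the sampling covariance of ``(V, V^2)`` across cones.  The mean
    and mean-square of the same cohort are strongly correlated; keeping
    that correlation is what makes the noise strength identifiable at
    realistic cohort sizes (see docs/methods.md).

Uncertainties come from a case-resampling bootstrap over growth cones
(or, when only moment series are available, from re-perturbing the series
values by their SEMs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import least_squares

from . import moments
from .analysis import MomentSeries, _dedupe
from .params import GrowthParams, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "FitError",
    "FitResult",
    "fit_mean_velocity",
    "fit_msv",
    "joint_fit",
    "predict_msl",
]

_GAMMA_LO, _GAMMA_HI = 1e-6, 50.0


class FitError(RuntimeError):
    """Raised when the optimiser fails to converge; carries diagnostics."""


def _mean_pred(t, a0, g, v0):
    vd = a0 / g
    return vd + (v0 - vd) * np.exp(-g * t)


def _msv_pred(t, a0, g, s2, v0):
    vd = a0 / g
    dv = v0 - vd
    e = np.exp(-g * t)
    return vd**2 + dv**2 * e**2 + 2.0 * vd * dv * e + s2 / (2.0 * g) * (1.0 - e**2)


def _check_series(series: MomentSeries, name: str, min_points: int = 3):
    if len(series) < min_points:
        raise ValidationError(f"{name} needs >= {min_points} time points")
    if np.any(series.sem <= 0):
        raise ValidationError(f"{name} requires strictly positive SEMs for weighting")


def fit_mean_velocity(series: MomentSeries, v0: float, start=None) -> dict:
    """Weighted least-squares fit of the mean-velocity relaxation curve.

    Returns ``{"a0", "gamma1", "objective"}``.  The starting point is a
    coarse grid over gamma1 in [0.01, 1] /hr with a0 profiled linearly
    (the model is linear in a0 at fixed gamma1), unless ``start=(a0,
    gamma1)`` is given.
    """
    _check_series(series, "mean-velocity series")
    t, y, w = series.t, series.value, 1.0 / series.sem**2

    if start is None:
        best = None
        for g in np.geomspace(0.01, 1.0, 40):
            e = np.exp(-g * t)
            b = (1.0 - e) / g
            off = v0 * e
            denom = np.sum(w * b * b)
            a0 = np.sum(w * b * (y - off)) / denom if denom > 0 else 0.0
            obj = float(np.sum(w * (_mean_pred(t, a0, g, v0) - y) ** 2))
            if best is None or obj < best[0]:
                best = (obj, a0, g)
        start = (best[1], best[2])

    sw = np.sqrt(w)

    def resid(theta):
        return sw * (_mean_pred(t, theta[0], theta[1], v0) - y)

    res = least_squares(resid, x0=list(start), bounds=([-np.inf, _GAMMA_LO], [np.inf, _GAMMA_HI]), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success:
        raise FitError(f"mean-velocity fit did not converge: {res.message} (status {res.status})")
    return {"a0": float(res.x[0]), "gamma1": float(res.x[1]), "objective": float(2.0 * res.cost)}


def fit_msv(series: MomentSeries, v0: float, fixed: Optional[dict] = None, start=None) -> dict:
    """Weighted fit of the mean-squared-velocity curve.

    With ``fixed={"a0":..., "gamma1":...}`` only sigma2 is estimated; the
    model is then linear in sigma2 and the weighted solution is closed
    form (clipped at the sigma2 >= 0 constraint, which is reported when
    active).  Otherwise all of (a0, gamma1, sigma2) are fit.
    """
    _check_series(series, "mean-squared-velocity series")
    t, y, w = series.t, series.value, 1.0 / series.sem**2

    if fixed is not None:
        a0, g = float(fixed["a0"]), float(fixed["gamma1"])
        s = (1.0 - np.exp(-2.0 * g * t)) / (2.0 * g)
        base = _msv_pred(t, a0, g, 0.0, v0)
        denom = np.sum(w * s * s)
        if denom <= 0:
            raise FitError("sigma2 not identifiable: all basis values vanish (t = 0 only?)")
        s2 = float(np.sum(w * s * (y - base)) / denom)
        if s2 < 0:
            logger.warning("sigma2 constraint active: unconstrained estimate %.4g clipped to 0", s2)
            s2 = 0.0
        obj = float(np.sum(w * (base + s2 * s - y) ** 2))
        return {"a0": a0, "gamma1": g, "sigma2": s2, "objective": obj, "constrained": s2 == 0.0}

    sw = np.sqrt(w)

    def resid(theta):
        return sw * (_msv_pred(t, theta[0], theta[1], theta[2], v0) - y)

    starts = []
    if start is not None:
        starts.append(list(start))
    else:
        y_last = max(float(y[-1]), 1e-12)
        for g in np.geomspace(0.01, 1.0, 10):
            a0 = g * math.sqrt(y_last)
            s2 = max(2.0 * g * (float(y[0]) - v0**2), 0.0) + 1e-3
            starts.append([a0, g, s2])
    best = None
    for x0 in starts:
        res = least_squares(
            resid, x0=x0,
            bounds=([-np.inf, _GAMMA_LO, 0.0], [np.inf, _GAMMA_HI, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("mean-squared-velocity fit did not converge from any starting point")
    return {
        "a0": float(best.x[0]), "gamma1": float(best.x[1]), "sigma2": float(best.x[2]),
        "objective": float(2.0 * best.cost), "constrained": bool(best.x[2] == 0.0),
    }


# ---------------------------------------------------------------------------
# joint estimation


def _sample_stats(samples: pd.DataFrame):
    """Per-time cohort statistics for the GLS objective.

    Returns (times, n, mean, msv, whiteners) where ``whiteners[i]`` maps
    the residual 2-vector (mean, msv) at time i to independent unit
    normals under the estimated sampling covariance of (V, V^2)/n.
    """
    per_cone = _dedupe(samples)
    times, ns, means, msvs, whiteners = [], [], [], [], []
    for t_obs, grp in per_cone.groupby("t_obs_hr", sort=True):
        v = grp["vx"].to_numpy(float)
        n = len(v)
        if n < 3:
            logger.warning("t_obs %s: fewer than 3 cones, dropped from GLS fit", t_obs)
            continue
        v2 = v**2
        cov = np.cov(np.vstack([v, v2]), ddof=1) / n
        # tiny ridge keeps the Cholesky factor well defined for degenerate cohorts
        ridge = 1e-12 * max(np.trace(cov), 1e-300)
        cov = cov + ridge * np.eye(2)
        L = cholesky(cov, lower=True)
        times.append(float(grp["t_mid_hr"].mean()))
        ns.append(n)
        means.append(v.mean())
        msvs.append(v2.mean())
        whiteners.append(L)
    if len(times) < 3:
        raise ValidationError("GLS fit needs >= 3 usable observation times")
    return (np.array(times), np.array(ns), np.array(means), np.array(msvs), whiteners)


def _joint_point(
    mean_series: MomentSeries,
    msv_series: MomentSeries,
    v0: float,
    mode: str,
    weights: str,
    samples: Optional[pd.DataFrame],
    start=None,
) -> dict:
    if mode == "sequential":
        mv = fit_mean_velocity(mean_series, v0)
        ms = fit_msv(msv_series, v0, fixed={"a0": mv["a0"], "gamma1": mv["gamma1"]})
        return {"a0": mv["a0"], "gamma1": mv["gamma1"], "sigma2": ms["sigma2"],
                "objective": mv["objective"] + ms["objective"]}
    if mode != "joint":
        raise ValidationError(f"unknown fit mode {mode!r}")

    if weights == "gls":
        if samples is None:
            raise ValidationError("weights='gls' requires per-cone velocity samples")
        t, _, mean_obs, msv_obs, whiteners = _sample_stats(samples)

        def resid(theta):
            a0, g, s2 = theta
            rm = _mean_pred(t, a0, g, v0) - mean_obs
            rs = _msv_pred(t, a0, g, s2, v0) - msv_obs
            out = np.empty(2 * len(t))
            for i, L in enumerate(whiteners):
                out[2 * i: 2 * i + 2] = solve_triangular(L, np.array([rm[i], rs[i]]), lower=True)
            return out
    else:
        _check_series(mean_series, "mean-velocity series")
        _check_series(msv_series, "mean-squared-velocity series")
        t1, y1, sw1 = mean_series.t, mean_series.value, 1.0 / mean_series.sem
        t2, y2, sw2 = msv_series.t, msv_series.value, 1.0 / msv_series.sem

        def resid(theta):
            a0, g, s2 = theta
            return np.concatenate([
                sw1 * (_mean_pred(t1, a0, g, v0) - y1),
                sw2 * (_msv_pred(t2, a0, g, s2, v0) - y2),
            ])

    if start is None:
        mv = fit_mean_velocity(mean_series, v0)
        ms = fit_msv(msv_series, v0, fixed={"a0": mv["a0"], "gamma1": mv["gamma1"]})
        start = (mv["a0"], mv["gamma1"], max(ms["sigma2"], 1e-6))
    res = least_squares(
        resid, x0=list(start),
        bounds=([-np.inf, _GAMMA_LO, 0.0], [np.inf, _GAMMA_HI, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise FitError(f"joint fit did not converge: {res.message} (status {res.status})")
    return {"a0": float(res.x[0]), "gamma1": float(res.x[1]), "sigma2": float(res.x[2]),
            "objective": float(2.0 * res.cost)}


@dataclass
class FitResult:
    """Point estimates, bootstrap uncertainties, and derived quantities."""

    params: GrowthParams
    v0: float
    D: float                     # diffusion coefficient, um^2/hr
    tau: float                   # characteristic time, hr
    mode: str
    weights: str
    objective: float
    n_boot: int = 0
    seed: Optional[int] = None
    ci: Optional[dict] = None              # {"a0": (lo, hi), ...} 95% percentile
    boot_draws: Optional[np.ndarray] = None  # (n_kept, 3) columns a0, gamma1, sigma2
    n_boot_failed: int = 0
    residuals: Optional[dict] = None

    @property
    def a0(self) -> float:
        return self.params.a0

    @property
    def gamma1(self) -> float:
        return self.params.gamma1

    @property
    def sigma2(self) -> float:
        return self.params.sigma2

    def to_dict(self) -> dict:
        d = {
            "a0_um_hr2": self.a0,
            "gamma1_per_hr": self.gamma1,
            "sigma2_um2_hr3": self.sigma2,
            "v0_um_hr": self.v0,
            "diffusion_um2_hr": self.D,
            "tau_hr": self.tau,
            "mode": self.mode,
            "weights": self.weights,
            "objective": self.objective,
            "n_boot": self.n_boot,
            "n_boot_failed": self.n_boot_failed,
            "seed": self.seed,
        }
        if self.ci is not None:
            d["ci95"] = {k: list(v) for k, v in self.ci.items()}
        return d

    def summary(self) -> str:
        lines = [
            "Axon growth model fit (drift + Ornstein-Uhlenbeck velocity)",
            f"  mode: {self.mode}   weights: {self.weights}   objective: {self.objective:.4g}",
            f"  V0 (fixed)          : {self.v0:.3f} um/hr",
        ]
        def _ci(name):
            if self.ci and name in self.ci:
                lo, hi = self.ci[name]
                return f"   [95% CI {lo:.3g}, {hi:.3g}]"
            return ""
        lines.append(f"  a0     (drift)      : {self.a0:.4g} um/hr^2{_ci('a0')}")
        lines.append(f"  gamma1 (damping)    : {self.gamma1:.4g} /hr{_ci('gamma1')}")
        lines.append(f"  sigma2 (noise)      : {self.sigma2:.4g} um^2/hr^3{_ci('sigma2')}")
        lines.append(f"  D = sigma2/(2 g^2)  : {self.D:.4g} um^2/hr")
        lines.append(f"  tau = 1/gamma1      : {self.tau:.4g} hr")
        if self.n_boot:
            lines.append(f"  bootstrap: {self.n_boot} replicates ({self.n_boot_failed} failed)")
        return "\n".join(lines)


def _case_resample(samples: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Resample growth cones with replacement within each observation time."""
    per_cone = _dedupe(samples)
    parts = []
    for _, grp in per_cone.groupby("t_obs_hr", sort=True):
        idx = rng.integers(0, len(grp), size=len(grp))
        part = grp.iloc[idx].copy()
        # resampled duplicates must stay distinct cones for _dedupe
        part["track_id"] = [f"{tid}#{k}" for k, tid in enumerate(part["track_id"])]
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def joint_fit(
    mean_series: MomentSeries,
    msv_series: MomentSeries,
    v0: float,
    mode: str = "joint",
    n_boot: int = 200,
    seed: Optional[int] = None,
    samples: Optional[pd.DataFrame] = None,
    weights: str = "auto",
    start=None,
) -> FitResult:
    """Estimate (a0, gamma1, sigma2) from both moment series.

    ``mode="joint"`` shares (a0, gamma1) across the two series in one
    weighted objective; ``mode="sequential"`` fits the mean-velocity curve
    first and then solves for sigma2 with (a0, gamma1) fixed.

    ``weights="auto"`` selects per-time GLS whitening when per-cone
    ``samples`` are supplied and diagonal 1/SEM^2 weights otherwise.
    Bootstrap CIs: case resampling over growth cones when samples are
    available, otherwise Gaussian re-perturbation of the series by their
    SEMs.
    """
    if weights == "auto":
        weights = "gls" if samples is not None else "sem"
    if weights not in ("gls", "sem"):
        raise ValidationError(f"unknown weights {weights!r}")

    point = _joint_point(mean_series, msv_series, v0, mode, weights, samples, start=start)
    params = GrowthParams(a0=point["a0"], gamma1=point["gamma1"], sigma2=point["sigma2"], v0_mean=v0)

    ci = None
    draws = None
    n_failed = 0
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        kept = []
        for _ in range(n_boot):
            try:
                if samples is not None:
                    boot = _case_resample(samples, rng)
                    from .analysis import ensemble_moments  # local import to avoid cycle

                    bm, bs = ensemble_moments(boot)
                    bp = _joint_point(bm, bs, v0, mode, weights, boot if weights == "gls" else None,
                                      start=(point["a0"], point["gamma1"], max(point["sigma2"], 1e-6)))
                else:
                    bm = MomentSeries(mean_series.t, mean_series.value + mean_series.sem * rng.standard_normal(len(mean_series)), mean_series.sem, mean_series.n)
                    bs = MomentSeries(msv_series.t, msv_series.value + msv_series.sem * rng.standard_normal(len(msv_series)), msv_series.sem, msv_series.n)
                    bp = _joint_point(bm, bs, v0, mode, "sem", None,
                                      start=(point["a0"], point["gamma1"], max(point["sigma2"], 1e-6)))
                kept.append((bp["a0"], bp["gamma1"], bp["sigma2"]))
            except (FitError, ValidationError) as exc:
                n_failed += 1
                logger.debug("bootstrap replicate failed: %s", exc)
        if n_failed:
            logger.warning("%d/%d bootstrap replicates failed", n_failed, n_boot)
        if len(kept) >= 10:
            draws = np.asarray(kept)
            qs = np.percentile(draws, [2.5, 97.5], axis=0)
            ci = {
                "a0": (float(qs[0, 0]), float(qs[1, 0])),
                "gamma1": (float(qs[0, 1]), float(qs[1, 1])),
                "sigma2": (float(qs[0, 2]), float(qs[1, 2])),
            }

    residuals = {
        "mean_velocity": np.asarray(moments.mean_velocity(params, mean_series.t)) - mean_series.value,
        "msv": np.asarray(moments.mean_squared_velocity(params, msv_series.t)) - msv_series.value,
    }
    return FitResult(
        params=params, v0=v0,
        D=moments.diffusion_coefficient(params), tau=moments.characteristic_time(params),
        mode=mode, weights=weights, objective=point["objective"],
        n_boot=int(n_boot or 0), seed=seed, ci=ci, boot_draws=draws,
        n_boot_failed=n_failed, residuals=residuals,
    )


def predict_msl(fit: FitResult, times) -> pd.DataFrame:
    """Mean-squared-length prediction at the fitted parameters.

    No refitting: the drift-free closed form is evaluated on the time
    grid.  When bootstrap draws are present, a pointwise 95% band is
    obtained by pushing each parameter draw through the same expression.
    """
    times = np.asarray(times, dtype=float)
    value = np.asarray(moments.mean_squared_length(fit.params, times))
    out = pd.DataFrame({"t_hr": times, "value": value})
    if fit.boot_draws is not None and len(fit.boot_draws):
        curves = np.empty((len(fit.boot_draws), len(times)))
        for i, (a0, g, s2) in enumerate(fit.boot_draws):
            p = GrowthParams(a0=a0, gamma1=max(g, _GAMMA_LO), sigma2=max(s2, 0.0), v0_mean=fit.v0)
            curves[i] = np.asarray(moments.mean_squared_length(p, times))
        out["lo"] = np.percentile(curves, 2.5, axis=0)
        out["hi"] = np.percentile(curves, 97.5, axis=0)
    return out
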