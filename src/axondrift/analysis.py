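"""Estimators computed from growth-cone track tables.

Velocities are frame-to-frame displacement ratios ``dr/dt``; by default
the increments inside one imaging window are averaged into a single
velocity sample per (track, observation time), which for equally spaced
frames equals the end-to-end displacement over the window length and
minimises the contribution of measurement noise.  Because that window
average estimates the mean velocity at the *midpoint* of the window, each
sample also carries ``t_mid_hr``; ensemble moment series are indexed by
the midpoint time so that model fits are not biased by the half-window
offset.

The growth angle convention: theta is measured from the +y axis,
``theta = atan2(dx, dy)`` wrapped to [0, 2pi), so theta = pi/2 is the +x
pattern direction and 3pi/2 the -x direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .params import ValidationError
from .protocol import is_persistent

logger = logging.getLogger(__name__)

__all__ = [
    "MomentSeries",
    "Histogram",
    "CorrelationEstimate",
    "estimate_velocities",
    "growth_angle",
    "velocity_histogram",
    "ensemble_moments",
    "correlation_estimator",
    "msl_estimator",
]


@dataclass(frozen=True)
class MomentSeries:
    """An ensemble moment estimate vs observation time with SEM and counts."""

    t: np.ndarray        # hr
    value: np.ndarray
    sem: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        for name in ("t", "value", "sem", "n"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (len(self.t) == len(self.value) == len(self.sem) == len(self.n)):
            raise ValidationError("MomentSeries fields must have equal length")
        if np.any(self.sem < 0) or np.any(self.n < 1):
            raise ValidationError("MomentSeries requires sem >= 0 and n >= 1")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_hr": self.t, "value": self.value, "sem": self.sem, "n": self.n})

    def to_csv(self, destination) -> None:
        self.to_frame().to_csv(destination, index=False, float_format="%.6f", lineterminator="\n")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MomentSeries":
        return cls(
            t=df["t_hr"].to_numpy(float),
            value=df["value"].to_numpy(float),
            sem=df["sem"].to_numpy(float),
            n=df["n"].to_numpy(int),
        )

    @classmethod
    def from_csv(cls, source) -> "MomentSeries":
        return cls.from_frame(pd.read_csv(source))


def growth_angle(dx: float, dy: float) -> float:
    """Growth angle from the displacement (dx, dy), radians in [0, 2pi).

    Measured from the +y axis; returns NaN for zero displacement
    (direction undefined).
    """
    if dx == 0.0 and dy == 0.0:
        return math.nan
    return math.atan2(dx, dy) % (2.0 * math.pi)


def estimate_velocities(
    table: pd.DataFrame,
    mode: str = "window",
    spacing_rtol: float = 1e-6,
    spacing_atol: float = 2e-6,
) -> pd.DataFrame:
    """Per-window velocity samples from a track table.

    mode "window" (default): one sample per (track_id, t_obs), the mean of
    the within-window increment ratios (= end-to-end displacement over the
    window span for equally spaced frames).  mode "increment": one sample
    per successive-frame increment.

    Windows with fewer than two frames or irregular frame spacing are
    rejected and logged.  Returns columns ``track_id, t_obs_hr, t_mid_hr,
    vx, vy, theta, n_increments``.
    """
    if mode not in ("window", "increment"):
        raise ValidationError(f"unknown mode {mode!r}")
    rows = []
    for (tid, t_obs), grp in table.groupby(["track_id", "t_obs_hr"], sort=True):
        grp = grp.sort_values("frame_index")
        times = grp["time_hr"].to_numpy(float)
        if len(times) < 2:
            logger.warning("window (track %r, t_obs %s): single frame, rejected", tid, t_obs)
            continue
        dts = np.diff(times)
        # atol covers the 1e-6 hr quantisation of the CSV dialect
        if np.any(np.abs(dts - dts[0]) > spacing_rtol * max(abs(dts[0]), 1e-12) + spacing_atol):
            logger.warning("window (track %r, t_obs %s): irregular frame spacing, rejected", tid, t_obs)
            continue
        xs = grp["x_um"].to_numpy(float)
        ys = grp["y_um"].to_numpy(float)
        if mode == "window":
            span = times[-1] - times[0]
            dx, dy = xs[-1] - xs[0], ys[-1] - ys[0]
            rows.append(
                (tid, float(t_obs), float(t_obs) + span / 2.0, dx / span, dy / span,
                 growth_angle(dx, dy), len(times) - 1)
            )
        else:
            for i in range(len(times) - 1):
                dx, dy = xs[i + 1] - xs[i], ys[i + 1] - ys[i]
                dt = times[i + 1] - times[i]
                rows.append(
                    (tid, float(t_obs), 0.5 * (times[i] + times[i + 1]), dx / dt, dy / dt,
                     growth_angle(dx, dy), 1)
                )
    return pd.DataFrame(rows, columns=["track_id", "t_obs_hr", "t_mid_hr", "vx", "vy", "theta", "n_increments"])


@dataclass(frozen=True)
class Histogram:
    """Equal-width normalized histogram (densities integrate to 1)."""

    edges: np.ndarray
    density: np.ndarray

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[1:] + self.edges[:-1])

    def mean(self) -> float:
        return float(np.sum(self.centers * self.density * self.widths))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_left": self.edges[:-1], "bin_right": self.edges[1:], "density": self.density})


def velocity_histogram(values, n_bins: Optional[int] = None) -> Histogram:
    """Equal-width normalized histogram of velocity samples.

    ``n_bins=None`` selects the bin count by the Freedman-Diaconis rule.
    Constant input occupies a single unit-width bin centred on the value.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("velocity_histogram requires non-empty input")
    if not np.all(np.isfinite(values)):
        raise ValidationError("velocity_histogram requires finite values")
    if n_bins is not None and n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        edges = np.array([lo - 0.5, hi + 0.5]) if n_bins in (None, 1) else np.linspace(lo - 0.5, hi + 0.5, n_bins + 1)
    elif n_bins is None:
        edges = np.histogram_bin_edges(values, bins="fd")
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    density, edges = np.histogram(values, bins=edges, density=True)
    return Histogram(edges=edges, density=density)


def _dedupe(samples: pd.DataFrame) -> pd.DataFrame:
    """Summarize to one row per (track_id, t_obs_hr) before aggregating."""
    return (
        samples.groupby(["track_id", "t_obs_hr"], sort=True)
        .agg(t_mid_hr=("t_mid_hr", "mean"), vx=("vx", "mean"), vy=("vy", "mean"))
        .reset_index()
    )


def ensemble_moments(
    samples: pd.DataFrame,
    absolute: bool = False,
    time: str = "mid",
) -> tuple[MomentSeries, MomentSeries]:
    """Mean velocity and mean squared velocity series across growth cones.

    Per observation time computes the mean and the mean of squares of the
    pattern-axis velocity over cones, with SEM = sample sd / sqrt(n).
    Signed velocities by default (``absolute=True`` averages |vx|).
    ``time`` selects the series time stamp: "mid" (window midpoint,
    default) or "obs" (window start).  Times with fewer than two cones are
    dropped with a warning.
    """
    if time not in ("mid", "obs"):
        raise ValidationError(f"unknown time convention {time!r}")
    per_cone = _dedupe(samples)
    mean_rows, msv_rows = [], []
    for t_obs, grp in per_cone.groupby("t_obs_hr", sort=True):
        n = len(grp)
        if n < 2:
            logger.warning("t_obs %s: fewer than 2 cones, dropped", t_obs)
            continue
        v = grp["vx"].to_numpy(float)
        if absolute:
            v = np.abs(v)
        t = float(grp["t_mid_hr"].mean()) if time == "mid" else float(t_obs)
        mean_rows.append((t, v.mean(), v.std(ddof=1) / math.sqrt(n), n))
        v2 = v**2
        msv_rows.append((t, v2.mean(), v2.std(ddof=1) / math.sqrt(n), n))
    if not mean_rows:
        raise ValidationError("no observation time has >= 2 growth cones")
    mk = lambda rows: MomentSeries(
        t=np.array([r[0] for r in rows]),
        value=np.array([r[1] for r in rows]),
        sem=np.array([r[2] for r in rows]),
        n=np.array([r[3] for r in rows]),
    )
    return mk(mean_rows), mk(msv_rows)


@dataclass(frozen=True)
class CorrelationEstimate:
    value: float     # um^2/hr^2
    n: int           # common growth cones


def correlation_estimator(samples: pd.DataFrame, t1: float, t2: float) -> CorrelationEstimate:
    """Cross-time velocity correlation ``<V(t1) V(t2)>`` over common cones.

    Averages ``V_i(t1) V_i(t2)`` over the growth cones present at both
    observation times; requires persistent-cohort data.
    """
    per_cone = _dedupe(samples)
    g1 = per_cone[per_cone["t_obs_hr"] == t1].set_index("track_id")["vx"]
    g2 = per_cone[per_cone["t_obs_hr"] == t2].set_index("track_id")["vx"]
    common = g1.index.intersection(g2.index)
    if len(common) == 0:
        raise ValidationError(
            f"no growth cones common to t_obs {t1} and {t2}; the cross-time "
            "correlation needs persistent-cohort tracks (persistent_tracks=True)"
        )
    prod = (g1.loc[common] * g2.loc[common]).to_numpy(float)
    return CorrelationEstimate(value=float(prod.mean()), n=len(common))


def msl_estimator(
    table: pd.DataFrame,
    reference: str = "drift_corrected",
    drift: float = 0.0,
) -> MomentSeries:
    """Empirical mean squared length from a persistent track table.

    Per observation time t, averages over tracks of the squared
    displacement of the window-start position from the track's initial
    position: raw mode ``(x(t) - x(0))^2``; drift_corrected mode
    ``(x(t) - x(0) - drift * t)^2``, the quantity the drift-free moment
    prediction describes (``drift`` is typically ``a0/gamma1``).
    """
    if reference not in ("raw", "drift_corrected"):
        raise ValidationError(f"unknown reference {reference!r}")
    if not is_persistent(table):
        raise ValidationError("msl_estimator requires a persistent-cohort table (same cones at every t_obs)")
    starts = (
        table[table["frame_index"] == 0]
        .set_index(["track_id", "t_obs_hr"])["x_um"]
        .sort_index()
    )
    obs_times = sorted(table["t_obs_hr"].unique())
    t0 = obs_times[0]
    x0 = starts.xs(t0, level="t_obs_hr")
    rows = []
    for t in obs_times:
        xt = starts.xs(t, level="t_obs_hr")
        disp = (xt - x0.loc[xt.index]).to_numpy(float)
        if reference == "drift_corrected":
            disp = disp - drift * (t - t0)
        sq = disp**2
        n = len(sq)
        sem = sq.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0
        rows.append((float(t), float(sq.mean()), float(sem), n))
    return MomentSeries(
        t=np.array([r[0] for r in rows]),
        value=np.array([r[1] for r in rows]),
        sem=np.array([r[2] for r in rows]),
        n=np.array([r[3] for r in rows]),
    )
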