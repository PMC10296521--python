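"""Synthetic growth-cone track tables emulating the imaging protocol.

The emulated experiment images growth cones on a micropatterned substrate
(pattern period 7 um) at observation times t = 0, 5, ..., 40 h, taking a
frame every 5 min for 30 min at each observation time, with a position
measurement precision of about 0.1 um and between 64 and 182 growth cones
per time point.  Motion is quasi-one-dimensional along the pattern axis
(x); the y coordinate carries only a small transverse jitter.

Tracks are exchanged as plain CSV with the fixed header
``track_id,t_obs_hr,frame_index,time_hr,x_um,y_um`` (UTF-8, '.' decimal
point, LF line endings, floats with 6 decimal places).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .params import GrowthParams, ValidationError
from .simulate import SimConfig, simulate_1d

__all__ = [
    "ProtocolConfig",
    "TrackFormatError",
    "TRACK_COLUMNS",
    "generate_experiment",
    "write_tracks",
    "read_tracks",
    "validate_tracks",
    "is_persistent",
]

TRACK_COLUMNS = ("track_id", "t_obs_hr", "frame_index", "time_hr", "x_um", "y_um")


class TrackFormatError(ValueError):
    """Raised when a track table violates the CSV schema or its invariants."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Observation-protocol settings for the synthetic experiment."""

    obs_times_hr: Sequence[float] = tuple(float(t) for t in range(0, 45, 5))
    frame_interval_min: float = 5.0
    window_length_min: float = 30.0
    #: cones per observation time: an int (same at every time), a sequence
    #: (one entry per observation time), or None to sample uniformly from
    #: [64, 182] as in the emulated experiment.
    n_per_obs: Union[int, Sequence[int], None] = None
    meas_noise_sd_um: float = 0.1
    persistent_tracks: bool = False
    transverse_jitter_sd_um: float = 0.2
    pattern_period_um: float = 7.0      # metadata only

    def __post_init__(self):
        obs = tuple(float(t) for t in self.obs_times_hr)
        object.__setattr__(self, "obs_times_hr", obs)
        if len(obs) == 0 or any(t < 0 for t in obs) or any(b <= a for a, b in zip(obs, obs[1:])):
            raise ValidationError("obs_times_hr must be non-negative and strictly increasing")
        if self.frame_interval_min <= 0 or self.window_length_min <= 0:
            raise ValidationError("frame_interval_min and window_length_min must be > 0")
        ratio = self.window_length_min / self.frame_interval_min
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError("frame_interval_min must divide window_length_min")
        if self.meas_noise_sd_um < 0 or self.transverse_jitter_sd_um < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if isinstance(self.n_per_obs, int) and self.n_per_obs < 1:
            raise ValidationError("n_per_obs must be >= 1")
        if isinstance(self.n_per_obs, Sequence) and not isinstance(self.n_per_obs, str):
            counts = tuple(int(n) for n in self.n_per_obs)
            object.__setattr__(self, "n_per_obs", counts)
            if len(counts) != len(obs):
                raise ValidationError("n_per_obs sequence must match obs_times_hr length")
            if any(n < 1 for n in counts):
                raise ValidationError("n_per_obs entries must be >= 1")

    @property
    def frames_per_window(self) -> int:
        return int(round(self.window_length_min / self.frame_interval_min))

    @property
    def frame_interval_hr(self) -> float:
        return self.frame_interval_min / 60.0

    @property
    def window_length_hr(self) -> float:
        return self.window_length_min / 60.0

    def cohort_sizes(self, rng: np.random.Generator) -> list[int]:
        if self.n_per_obs is None:
            if self.persistent_tracks:
                return [int(rng.integers(64, 183))] * len(self.obs_times_hr)
            return [int(n) for n in rng.integers(64, 183, size=len(self.obs_times_hr))]
        if isinstance(self.n_per_obs, int):
            return [self.n_per_obs] * len(self.obs_times_hr)
        counts = list(self.n_per_obs)
        if self.persistent_tracks and len(set(counts)) != 1:
            raise ValidationError("persistent_tracks requires a constant cohort size")
        return counts


def _window_rows(table, track_ids, t_obs, times, xs, ys):
    n_frames = xs.shape[1]
    for i, tid in enumerate(track_ids):
        for j in range(n_frames):
            table.append((tid, t_obs, j, times[j], xs[i, j], ys[i, j]))


def generate_experiment(
    params: GrowthParams,
    proto: ProtocolConfig = ProtocolConfig(),
    seed: int = 0,
    init_velocity_sd: float = 1.0,
) -> pd.DataFrame:
    """Generate a synthetic track table under the imaging protocol.

    For every observation time an independent cohort of 1D paths is
    simulated from t = 0 with the exact drift-OU scheme and its positions
    are recorded at the window frames; with ``persistent_tracks`` a single
    cohort is followed across all observation windows instead.  I.i.d.
    Gaussian measurement noise (``meas_noise_sd_um``) is added to every
    recorded coordinate, and y holds i.i.d. transverse jitter.

    Returns a :data:`TRACK_COLUMNS` DataFrame; positions are absolute
    along the simulated path (every estimator downstream uses
    displacements only).
    """
    master = np.random.SeedSequence(int(seed))
    size_rng = np.random.default_rng(master.spawn(1)[0])
    sizes = proto.cohort_sizes(size_rng)
    dt = proto.frame_interval_hr
    k = proto.frames_per_window
    rows: list[tuple] = []

    def _measure(rng, shape):
        return rng.normal(0.0, proto.meas_noise_sd_um, size=shape) if proto.meas_noise_sd_um > 0 else 0.0

    if proto.persistent_tracks:
        n = sizes[0]
        duration = proto.obs_times_hr[-1] + proto.window_length_hr
        cfg = SimConfig(
            dt=dt, duration=duration, n_tracks=n, seed=int(seed),
            init_velocity_mean=params.v0_mean, init_velocity_sd=init_velocity_sd,
        )
        sim = simulate_1d(params, cfg)
        noise_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 10_007]))
        track_ids = [f"c{i:04d}" for i in range(n)]
        for t_obs in proto.obs_times_hr:
            i0 = int(round(t_obs / dt))
            idx = np.arange(i0, i0 + k + 1)
            times = sim.times[idx]
            xs = sim.position[:, idx] + _measure(noise_rng, (n, k + 1))
            ys = noise_rng.normal(0.0, proto.transverse_jitter_sd_um, size=(n, k + 1)) + _measure(
                noise_rng, (n, k + 1)
            )
            _window_rows(rows, track_ids, t_obs, times, xs, ys)
    else:
        for j, (t_obs, n) in enumerate(zip(proto.obs_times_hr, sizes)):
            cfg = SimConfig(
                dt=dt, duration=t_obs + proto.window_length_hr, n_tracks=n,
                seed=int(np.random.SeedSequence([int(seed), 1_000_003 + j]).generate_state(1)[0] % 2**31),
                init_velocity_mean=params.v0_mean, init_velocity_sd=init_velocity_sd,
            )
            sim = simulate_1d(params, cfg)
            i0 = int(round(t_obs / dt))
            idx = np.arange(i0, i0 + k + 1)
            noise_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 20_011 + j]))
            track_ids = [f"obs{j}_c{i:04d}" for i in range(n)]
            times = sim.times[idx]
            xs = sim.position[:, idx] + _measure(noise_rng, (n, k + 1))
            ys = noise_rng.normal(0.0, proto.transverse_jitter_sd_um, size=(n, k + 1)) + _measure(
                noise_rng, (n, k + 1)
            )
            _window_rows(rows, track_ids, t_obs, times, xs, ys)

    df = pd.DataFrame(rows, columns=list(TRACK_COLUMNS))
    df["frame_index"] = df["frame_index"].astype(int)
    return df


def validate_tracks(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Validate a track table against the schema invariants.

    Checks column presence, numeric finite coordinates, and per
    (track_id, t_obs) windows with unique frame indices 0..k and strictly
    increasing times.  Raises :class:`TrackFormatError` naming the
    offending window and data line (header = line 1).
    """
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{source}: missing columns {missing}")
    df = df.loc[:, list(TRACK_COLUMNS)].copy()
    for col in ("t_obs_hr", "time_hr", "x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise TrackFormatError(f"{source}: non-numeric or non-finite {col} at line {line}")
        df[col] = vals.astype(float)
    try:
        df["frame_index"] = df["frame_index"].astype(int)
    except (TypeError, ValueError) as exc:
        raise TrackFormatError(f"{source}: non-integer frame_index") from exc

    for (tid, t_obs), grp in df.groupby(["track_id", "t_obs_hr"], sort=False):
        frames = grp["frame_index"].to_numpy()
        times = grp["time_hr"].to_numpy()
        if len(np.unique(frames)) != len(frames):
            line = int(grp.index[0]) + 2
            raise TrackFormatError(
                f"{source}: duplicated frame_index in window (track {tid!r}, t_obs {t_obs}) near line {line}"
            )
        order = np.argsort(frames)
        if not np.array_equal(frames[order], np.arange(len(frames))):
            line = int(grp.index[0]) + 2
            raise TrackFormatError(
                f"{source}: frame_index must run 0..k in window (track {tid!r}, t_obs {t_obs}) near line {line}"
            )
        if np.any(np.diff(times[order]) <= 0):
            line = int(grp.index[0]) + 2
            raise TrackFormatError(
                f"{source}: non-increasing frame times in window (track {tid!r}, t_obs {t_obs}) near line {line}"
            )
    return df


def write_tracks(df: pd.DataFrame, destination) -> None:
    """Write a track table to CSV in the fixed dialect (lossless to 1e-6 um)."""
    out = df.loc[:, list(TRACK_COLUMNS)]
    out.to_csv(destination, index=False, float_format="%.6f", lineterminator="\n")


def read_tracks(source) -> pd.DataFrame:
    """Read and validate a track CSV; structured errors carry line numbers."""
    try:
        df = pd.read_csv(source, dtype={"track_id": str})
    except pd.errors.EmptyDataError as exc:
        raise TrackFormatError(f"{source}: empty file (no header)") from exc
    return validate_tracks(df, source=str(source))


def is_persistent(df: pd.DataFrame) -> bool:
    """True when the same track ids are present at every observation time."""
    groups = df.groupby("t_obs_hr")["track_id"].agg(frozenset)
    return len(groups) > 0 and len(set(groups)) == 1
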