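"""Model/Results interface for the biased-random-walk growth model.

    >>> model = AxonGrowthModel.from_tracks(table)
    >>> res = model.fit(n_boot=200, seed=1)
    >>> print(res.summary())
    >>> res.predict_msl([0, 5, 10])

`AxonGrowthModel` holds the data (per-cone velocity samples and/or
ensemble moment series plus the fixed initial mean velocity V0);
``fit()`` returns an `AxonGrowthResults` carrying the estimates, their
bootstrap confidence intervals, the derived diffusion coefficient and
characteristic time, predictions, simulation, and plotting.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import fitting, moments
from .analysis import MomentSeries, ensemble_moments, estimate_velocities
from .params import GrowthParams, ValidationError
from .simulate import SimConfig, SimResult1D, simulate_1d

__all__ = ["AxonGrowthModel", "AxonGrowthResults"]


class AxonGrowthModel:
    """Drift + Ornstein-Uhlenbeck velocity model bound to track data."""

    def __init__(
        self,
        mean_series: MomentSeries,
        msv_series: MomentSeries,
        v0: float,
        samples: Optional[pd.DataFrame] = None,
    ):
        self.mean_series = mean_series
        self.msv_series = msv_series
        self.v0 = float(v0)
        self.samples = samples

    @classmethod
    def from_tracks(cls, table: pd.DataFrame, v0: Optional[float] = None) -> "AxonGrowthModel":
        """Build the model from a track table.

        Velocities are estimated per imaging window; ``v0`` defaults to
        the mean pattern-axis velocity at the earliest observation time
        (the empirical t = 0 distribution mean).
        """
        samples = estimate_velocities(table)
        if samples.empty:
            raise ValidationError("no usable velocity windows in the track table")
        mean_series, msv_series = ensemble_moments(samples)
        if v0 is None:
            t0 = samples["t_obs_hr"].min()
            v0 = float(samples.loc[samples["t_obs_hr"] == t0, "vx"].mean())
        return cls(mean_series, msv_series, v0, samples=samples)

    @classmethod
    def from_samples(cls, samples: pd.DataFrame, v0: Optional[float] = None) -> "AxonGrowthModel":
        """Build the model from per-cone velocity samples."""
        mean_series, msv_series = ensemble_moments(samples)
        if v0 is None:
            t0 = samples["t_obs_hr"].min()
            v0 = float(samples.loc[samples["t_obs_hr"] == t0, "vx"].mean())
        return cls(mean_series, msv_series, v0, samples=samples)

    def fit(
        self,
        mode: str = "joint",
        n_boot: int = 200,
        seed: Optional[int] = None,
        weights: str = "auto",
    ) -> "AxonGrowthResults":
        result = fitting.joint_fit(
            self.mean_series, self.msv_series, self.v0,
            mode=mode, n_boot=n_boot, seed=seed,
            samples=self.samples, weights=weights,
        )
        return AxonGrowthResults(self, result)


class AxonGrowthResults:
    """Fit results: estimates, uncertainties, diagnostics, predictions."""

    def __init__(self, model: AxonGrowthModel, result: fitting.FitResult):
        self.model = model
        self._result = result

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> GrowthParams:
        return self._result.params

    @property
    def a0(self) -> float:
        return self._result.a0

    @property
    def gamma1(self) -> float:
        return self._result.gamma1

    @property
    def sigma2(self) -> float:
        return self._result.sigma2

    @property
    def diffusion_coefficient(self) -> float:
        """D = sigma2 / (2 gamma1^2), um^2/hr."""
        return self._result.D

    @property
    def characteristic_time(self) -> float:
        """tau = 1/gamma1, hr."""
        return self._result.tau

    @property
    def fit_result(self) -> fitting.FitResult:
        return self._result

    def conf_int(self) -> pd.DataFrame:
        """95% bootstrap confidence intervals (rows: a0, gamma1, sigma2)."""
        if self._result.ci is None:
            raise ValidationError("no bootstrap confidence intervals: refit with n_boot > 0")
        rows = {k: list(v) for k, v in self._result.ci.items()}
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    # -- predictions -------------------------------------------------------
    def predict_mean_velocity(self, t):
        return moments.mean_velocity(self.params, t)

    def predict_msv(self, t):
        return moments.mean_squared_velocity(self.params, t)

    def predict_msl(self, t) -> pd.DataFrame:
        """Mean-squared-length curve (with bootstrap band when available)."""
        return fitting.predict_msl(self._result, t)

    def simulate(self, n_tracks: int, duration: float, dt: float = 0.25, seed: int = 0,
                 init_velocity_sd: float = 1.0) -> SimResult1D:
        """Simulate growth-cone paths at the fitted parameters."""
        cfg = SimConfig(dt=dt, duration=duration, n_tracks=n_tracks, seed=seed,
                        init_velocity_mean=self.model.v0, init_velocity_sd=init_velocity_sd)
        return simulate_1d(self.params, cfg)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        return self._result.summary()

    def to_dict(self) -> dict:
        return self._result.to_dict()

    def plot_fit(self, axes=None):
        """Plot the two moment series with the fitted curves.

        Returns the (ax_mean, ax_msv) pair; creates a new figure when no
        axes are supplied.
        """
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        ax_mean, ax_msv = axes
        ms, ss = self.model.mean_series, self.model.msv_series
        grid = np.linspace(0.0, float(max(ms.t.max(), ss.t.max())), 200)
        ax_mean.errorbar(ms.t, ms.value, yerr=ms.sem, fmt="o", ms=4, label="data")
        ax_mean.plot(grid, self.predict_mean_velocity(grid), "-", label="fit")
        ax_mean.set_xlabel("t (hr)")
        ax_mean.set_ylabel(r"$\langle V \rangle$ ($\mu$m/hr)")
        ax_mean.legend()
        ax_msv.errorbar(ss.t, ss.value, yerr=ss.sem, fmt="o", ms=4, label="data")
        ax_msv.plot(grid, self.predict_msv(grid), "-", label="fit")
        ax_msv.set_xlabel("t (hr)")
        ax_msv.set_ylabel(r"$\langle V^2 \rangle$ ($\mu$m$^2$/hr$^2$)")
        ax_msv.legend()
        return axes

    def plot_msl(self, t=None, ax=None):
        """Plot the predicted mean-squared-length curve with its band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if t is None:
            t = np.linspace(0.0, float(self.model.mean_series.t.max()), 200)
        pred = self.predict_msl(t)
        ax.plot(pred["t_hr"], pred["value"], "-", label="prediction")
        if "lo" in pred:
            ax.fill_between(pred["t_hr"], pred["lo"], pred["hi"], alpha=0.3, label="95% band")
        ax.set_xlabel("t (hr)")
        ax.set_ylabel(r"$\langle L^2 \rangle$ ($\mu$m$^2$)")
        ax.legend()
        return ax
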