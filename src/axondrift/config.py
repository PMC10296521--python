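"""Structured run configuration for the command-line pipeline.

One YAML file drives every stage.  Keys are flat and unit-suffixed::

    seed: 1
    params:
      a0_um_hr2: 3.1
      gamma1_per_hr: 0.11
      sigma2_um2_hr3: 0.52
      v0_mean_um_hr: 0.9
    protocol:
      obs_times_hr: [0, 5, 10, 15, 20, 25, 30, 35, 40]
      frame_interval_min: 5
      window_length_min: 30
      n_per_obs: 150          # int, list, or null to sample 64..182
      meas_noise_sd_um: 0.1
      persistent_tracks: false
      transverse_jitter_sd_um: 0.2
      pattern_period_um: 7.0
    sim:
      init_velocity_sd_um_hr: 1.0
    fitting:
      mode: joint             # joint | sequential
      n_boot: 200
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .params import GrowthParams, ValidationError
from .protocol import ProtocolConfig

__all__ = ["RunConfig"]

_PARAM_KEYS = {
    "a0_um_hr2": "a0",
    "gamma1_per_hr": "gamma1",
    "sigma2_um2_hr3": "sigma2",
    "v0_mean_um_hr": "v0_mean",
}


@dataclass
class RunConfig:
    params: GrowthParams = GrowthParams(a0=3.1, gamma1=0.11, sigma2=0.52, v0_mean=0.9)
    protocol: ProtocolConfig = field(default_factory=lambda: ProtocolConfig(n_per_obs=150))
    init_velocity_sd: float = 1.0
    fit_mode: str = "joint"
    n_boot: int = 200
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        if "params" in d:
            p = d["params"]
            unknown = set(p) - set(_PARAM_KEYS)
            if unknown:
                raise ValidationError(f"unknown params keys: {sorted(unknown)}")
            kwargs["params"] = GrowthParams(**{_PARAM_KEYS[k]: float(v) for k, v in p.items()})
        if "protocol" in d:
            proto = dict(d["protocol"])
            if isinstance(proto.get("obs_times_hr"), list):
                proto["obs_times_hr"] = tuple(proto["obs_times_hr"])
            kwargs["protocol"] = ProtocolConfig(**proto)
        if "sim" in d:
            kwargs["init_velocity_sd"] = float(d["sim"].get("init_velocity_sd_um_hr", 1.0))
        if "fitting" in d:
            kwargs["fit_mode"] = d["fitting"].get("mode", "joint")
            kwargs["n_boot"] = int(d["fitting"].get("n_boot", 200))
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        p = self.params
        proto = self.protocol
        return {
            "seed": self.seed,
            "params": {
                "a0_um_hr2": p.a0,
                "gamma1_per_hr": p.gamma1,
                "sigma2_um2_hr3": p.sigma2,
                "v0_mean_um_hr": p.v0_mean,
            },
            "protocol": {
                "obs_times_hr": list(proto.obs_times_hr),
                "frame_interval_min": proto.frame_interval_min,
                "window_length_min": proto.window_length_min,
                "n_per_obs": list(proto.n_per_obs) if isinstance(proto.n_per_obs, tuple) else proto.n_per_obs,
                "meas_noise_sd_um": proto.meas_noise_sd_um,
                "persistent_tracks": proto.persistent_tracks,
                "transverse_jitter_sd_um": proto.transverse_jitter_sd_um,
                "pattern_period_um": proto.pattern_period_um,
            },
            "sim": {"init_velocity_sd_um_hr": self.init_velocity_sd},
            "fitting": {"mode": self.fit_mode, "n_boot": self.n_boot},
        }

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(payload).hexdigest()[:16]
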