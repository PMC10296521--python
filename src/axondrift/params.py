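"""Parameter containers for the axonal growth models.

The reduced quasi-one-dimensional model describes the growth-cone velocity
``V`` along the micropattern axis as an Ornstein-Uhlenbeck process with a
constant drift acceleration,

    dV/dt = a0 - gamma1 * V + Gamma(t),

where ``Gamma`` is Gaussian white noise with ``<Gamma(t1) Gamma(t2)> =
sigma2 * delta(t1 - t2)``.  The full planar model adds a quadratic damping
term and a deterministic aligning torque perpendicular to the motion.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, fields


class ValidationError(ValueError):
    """Raised when a parameter set or an operation input is invalid."""


def _require_finite(obj, names):
    for name in names:
        value = getattr(obj, name)
        if not isinstance(value, (int, float)) or not math.isfinite(value):
            raise ValidationError(f"{type(obj).__name__}.{name} must be a finite number, got {value!r}")


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the reduced 1D drift-OU growth model.

    Attributes
    ----------
    a0 : float
        Constant drift acceleration imparted by the substrate geometry,
        um/hr^2.
    gamma1 : float
        Linear velocity-damping rate, 1/hr.  The velocity relaxation
        (characteristic) time is ``tau = 1/gamma1``.
    sigma2 : float
        White-noise strength (variance of the stochastic acceleration),
        um^2/hr^3.
    v0_mean : float
        Mean initial growth-cone velocity ``V0``, um/hr.
    """

    a0: float
    gamma1: float
    sigma2: float
    v0_mean: float = 0.0

    def __post_init__(self):
        _require_finite(self, ("a0", "gamma1", "sigma2", "v0_mean"))
        if self.gamma1 <= 0:
            raise ValidationError(f"gamma1 must be > 0, got {self.gamma1}")
        if self.sigma2 < 0:
            raise ValidationError(f"sigma2 must be >= 0, got {self.sigma2}")

    @property
    def drift_velocity(self) -> float:
        """Terminal mean velocity ``a0 / gamma1``, um/hr."""
        return self.a0 / self.gamma1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthParams":
        names = {f.name for f in fields(cls)}
        return cls(**{k: float(v) for k, v in d.items() if k in names})


@dataclass(frozen=True)
class FullModelParams2D:
    """Parameters of the full planar growth model.

    The parallel acceleration is ``a0 |sin(theta)| - gamma1 V - gamma2 V^2
    + Gamma(t)`` and the perpendicular one ``a1 cos(theta) +
    Gamma_perp(t)``; ``theta`` is the growth angle measured from the y axis
    so that ``theta = pi/2`` points along the pattern (+x).

    Defaults for ``gamma1`` (0.1 /hr) and ``gamma2`` (1e-3 /um) are the
    values measured for 7 um-period micropatterned PDMS substrates.
    """

    a0: float
    a1: float
    gamma1: float = 0.1
    gamma2: float = 1e-3
    sigma2_par: float = 0.0
    sigma2_perp: float = 0.0

    def __post_init__(self):
        _require_finite(self, ("a0", "a1", "gamma1", "gamma2", "sigma2_par", "sigma2_perp"))
        if self.gamma1 <= 0:
            raise ValidationError(f"gamma1 must be > 0, got {self.gamma1}")
        if self.gamma2 < 0:
            raise ValidationError(f"gamma2 must be >= 0, got {self.gamma2}")
        if self.sigma2_par < 0 or self.sigma2_perp < 0:
            raise ValidationError("noise variances must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


#: Fitted parameter set for embryonic cortical axons on PDL-coated PDMS
#: with 7 um pattern period (observation window 0-40 h).
CORTICAL_PDMS_D7 = GrowthParams(a0=3.1, gamma1=0.11, sigma2=0.52, v0_mean=0.9)
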