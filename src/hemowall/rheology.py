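"""Carreau generalized-Newtonian blood rheology.

Blood is shear-thinning: its apparent viscosity falls from a zero-shear
plateau ``mu_zero`` to an infinite-shear plateau ``mu_inf`` as the shear
rate grows.  The Carreau model interpolates between the two plateaus,

    mu(gdot) = mu_inf + (mu_zero - mu_inf) * [1 + (lambda*gdot)^2]^((n-1)/2)

with time constant ``lambda`` (s) and power-law index ``n``.  For n < 1 the
law is monotonically non-increasing in the shear rate and bounded by the
two plateaus.  The default parameter set is the one commonly used for
human blood in large-artery CFD (mu_zero = 0.056 Pa*s, mu_inf = 0.0035 Pa*s,
lambda = 3.313 s, n = 0.568, density 1060 kg/m^3).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["CarreauParameters", "BLOOD", "carreau_viscosity", "apparent_viscosity_range"]


@dataclass(frozen=True)
class CarreauParameters:
    """Constants of the Carreau viscosity law plus the fluid density.

    Parameters
    ----------
    mu_zero : float
        Zero-shear-rate viscosity plateau, Pa*s.
    mu_inf : float
        Infinite-shear-rate viscosity plateau, Pa*s.  Must satisfy
        ``0 < mu_inf <= mu_zero``.
    lambda_s : float
        Relaxation time constant, s.
    n_index : float
        Power-law index.  Shear-thinning requires ``0 < n_index <= 1``;
        values above 1 (shear-thickening) are rejected unless
        ``allow_shear_thickening`` is set.
    rho : float
        Fluid density, kg/m^3.
    """

    mu_zero: float
    mu_inf: float
    lambda_s: float
    n_index: float
    rho: float
    allow_shear_thickening: bool = False

    def __post_init__(self) -> None:
        if not (self.mu_inf > 0):
            raise ValueError(f"mu_inf must be positive, got {self.mu_inf}")
        if not (self.mu_zero >= self.mu_inf):
            raise ValueError(
                f"mu_zero ({self.mu_zero}) must be >= mu_inf ({self.mu_inf})"
            )
        if not (self.lambda_s > 0):
            raise ValueError(f"lambda_s must be positive, got {self.lambda_s}")
        if not (self.rho > 0):
            raise ValueError(f"rho must be positive, got {self.rho}")
        if not (self.n_index > 0):
            raise ValueError(f"n_index must be positive, got {self.n_index}")
        if self.n_index > 1 and not self.allow_shear_thickening:
            raise ValueError(
                f"n_index = {self.n_index} > 1 is shear-thickening; "
                "set allow_shear_thickening=True to permit it"
            )

    @classmethod
    def newtonian(cls, mu: float, rho: float) -> "CarreauParameters":
        """Degenerate constant-viscosity parameter set (mu_zero == mu_inf)."""
        return cls(mu_zero=mu, mu_inf=mu, lambda_s=1.0, n_index=1.0, rho=rho)

    @classmethod
    def from_dict(cls, d: dict) -> "CarreauParameters":
        known = {"mu_zero", "mu_inf", "lambda_s", "n_index", "rho", "allow_shear_thickening"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown rheology keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


#: Reference human-blood parameter set for large-artery simulations.
BLOOD = CarreauParameters(mu_zero=0.056, mu_inf=0.0035, lambda_s=3.313, n_index=0.568, rho=1060.0)


def carreau_viscosity(params: CarreauParameters, shear_rate):
    """Apparent viscosity mu(gdot) in Pa*s for a non-negative shear rate.

    Accepts a scalar or an array of shear-rate magnitudes (1/s) and returns
    the viscosity with the same shape.  Negative shear rates are a domain
    error: callers are expected to pass magnitudes.
    """
    gdot = np.asarray(shear_rate, dtype=float)
    if np.any(gdot < 0):
        raise ValueError("shear_rate must be non-negative (pass magnitudes)")
    mu = params.mu_inf + (params.mu_zero - params.mu_inf) * (
        1.0 + (params.lambda_s * gdot) ** 2
    ) ** ((params.n_index - 1.0) / 2.0)
    if np.isscalar(shear_rate) or np.ndim(shear_rate) == 0:
        return float(mu)
    return mu


def apparent_viscosity_range(params: CarreauParameters) -> tuple[float, float]:
    """Attainable viscosity band ``(mu_min, mu_max) = (mu_inf, mu_zero)``.

    For a shear-thinning law every viscosity value lies in this closed band,
    approached at infinite and zero shear rate respectively.
    """
    return (params.mu_inf, params.mu_zero)
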