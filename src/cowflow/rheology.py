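"""Shear-thinning blood rheology.

Blood is modelled as a Carreau fluid: apparent viscosity interpolates
between a zero-shear plateau ``mu_zero`` and an infinite-shear plateau
``mu_inf`` as

    mu(gamma) = mu_inf + (mu_zero - mu_inf) * [1 + (lambda*gamma)^2]^((n-1)/2)

with relaxation time ``lambda`` (s) and power index ``n`` < 1.  For the
reduced-order network each cylindrical segment is assigned a single
representative shear rate, the Poiseuille wall shear rate
``32*Q/(pi*d^3)``, which couples the viscosity to the segment flow.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .units import MM3_PER_ML

__all__ = [
    "CarreauParameters",
    "carreau_viscosity",
    "wall_shear_rate",
    "effective_viscosity",
]


@dataclass(frozen=True)
class CarreauParameters:
    """Constants of the Carreau viscosity law for whole blood.

    Defaults are the values commonly fitted to human blood:
    lambda = 3.313 s, n = 0.3568, mu0 = 0.056 Pa·s, mu_inf = 0.00345 Pa·s.

    Attributes
    ----------
    relaxation_time : float
        Carreau time constant lambda, seconds.
    power_index : float
        Power-law index n, dimensionless, 0 < n < 1.
    mu_zero : float
        Zero-shear viscosity, Pa·s.
    mu_inf : float
        Infinite-shear viscosity, Pa·s.
    """

    relaxation_time: float = 3.313
    power_index: float = 0.3568
    mu_zero: float = 0.056
    mu_inf: float = 0.00345

    def __post_init__(self) -> None:
        if not self.mu_inf > 0:
            raise ValueError(f"mu_inf must be positive, got {self.mu_inf}")
        if not self.mu_zero >= self.mu_inf:
            raise ValueError(
                f"mu_zero ({self.mu_zero}) must be >= mu_inf ({self.mu_inf})")
        if not 0 < self.power_index < 1:
            raise ValueError(
                f"power_index must lie in (0, 1), got {self.power_index}")
        if not self.relaxation_time > 0:
            raise ValueError(
                f"relaxation_time must be positive, got {self.relaxation_time}")


def carreau_viscosity(shear_rate: float,
                      params: CarreauParameters = CarreauParameters()) -> float:
    """Apparent viscosity (Pa·s) at a given shear rate (1/s).

    Strictly decreasing in shear rate (for mu_zero > mu_inf), bounded by
    [mu_inf, mu_zero]; equals mu_zero exactly at zero shear.
    """
    if shear_rate < 0:
        raise ValueError(f"shear_rate must be >= 0, got {shear_rate}")
    x = params.relaxation_time * shear_rate
    return params.mu_inf + (params.mu_zero - params.mu_inf) * (
        1.0 + x * x) ** ((params.power_index - 1.0) / 2.0)


def wall_shear_rate(flow_ml_s: float, diameter_mm: float) -> float:
    """Poiseuille wall shear rate 32*Q/(pi*d^3) in 1/s.

    This scalar stands in for the full shear field of a segment; it uses
    the magnitude of the flow, so the result is sign-independent, and is
    exactly zero at zero flow.
    """
    if diameter_mm <= 0:
        raise ValueError(f"diameter must be positive, got {diameter_mm}")
    q_mm3_s = abs(flow_ml_s) * MM3_PER_ML
    return 32.0 * q_mm3_s / (math.pi * diameter_mm ** 3)


def effective_viscosity(flow_ml_s: float, diameter_mm: float,
                        params: CarreauParameters = CarreauParameters()) -> float:
    """Carreau viscosity evaluated at the segment's wall shear rate."""
    return carreau_viscosity(wall_shear_rate(flow_ml_s, diameter_mm), params)
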