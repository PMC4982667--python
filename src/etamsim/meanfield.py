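"""Mean-field density-velocity relation of torque-coupled polymerase traffic.

Linearizing the torque response around the preferred spacing ``L0`` (the
spacing at which both flanking DNA segments are relaxed) turns the
stochastic hop dynamics into a car-following-like velocity law

    v(rho) = C ln(1 + 2 L0 (rho0 - rho)) + beta,      rho0 = 1 / L0,

where ``C > 0`` collects the torque prefactor and the (linearized) slope of
the torque-velocity response, and ``beta`` is the zero-torque elongation
velocity.  Densities above the preferred density ``rho0`` slow the
polymerases down and densities below speed them up — a negative feedback
that explains the observed synchronization of neighboring polymerases.
``C`` and ``beta`` are supplied by the user rather than derived, since the
reduction fixes them only up to the choice of linearized response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MeanFieldParams", "mean_velocity", "mean_velocity_slope", "velocity_table"]


@dataclass(frozen=True)
class MeanFieldParams:
    """Sensitivity C (nt/s), base velocity beta (nt/s), preferred spacing L0 (nt)."""

    sensitivity: float
    base_velocity: float
    preferred_spacing: float

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.preferred_spacing <= 0:
            raise ValueError("preferred spacing must be positive")

    @property
    def preferred_density(self) -> float:
        return 1.0 / self.preferred_spacing


def _log_argument(params: MeanFieldParams, rho: float) -> float:
    arg = 1.0 + 2.0 * params.preferred_spacing * (params.preferred_density - rho)
    if arg <= 0:
        raise ValueError(
            f"density {rho} outside the domain of the mean-field velocity"
        )
    return arg


def mean_velocity(params: MeanFieldParams, rho: float) -> float:
    """Steady-state polymerase velocity (nt/s) at density ``rho`` (1/nt).

    Equals ``base_velocity`` exactly at the preferred density and decreases
    strictly with density.
    """
    return params.sensitivity * math.log(_log_argument(params, rho)) + params.base_velocity


def mean_velocity_slope(params: MeanFieldParams, rho: float) -> float:
    """d(velocity)/d(density); negative everywhere on the domain."""
    return -2.0 * params.sensitivity * params.preferred_spacing / _log_argument(
        params, rho
    )


def velocity_table(
    params: MeanFieldParams, rhos: np.ndarray | list[float]
) -> pd.DataFrame:
    """Tabulate (density, velocity, slope) for a grid of densities."""
    rows = [
        {
            "density": float(r),
            "velocity": mean_velocity(params, float(r)),
            "slope": mean_velocity_slope(params, float(r)),
        }
        for r in np.asarray(rhos, dtype=float)
    ]
    return pd.DataFrame(rows)
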