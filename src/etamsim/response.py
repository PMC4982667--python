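"""Fitted torque-response functions: velocity, pause frequency, pause duration.

Single-molecule optical-trap measurements give the elongation velocity
``V(tau)`` (nt/s), the probability per translocation step of entering a pause
``F(tau)``, and the mean pause duration ``D(tau)`` (s) of an RNA polymerase
as functions of the torque ``tau`` (pN nm) it experiences.  Several fit
families are provided:

* ``nonlinear`` -- a fifth-order polynomial for V, a piecewise quadratic for
  F anchored at pause probability 1 at the ~11 pN nm stall torque, and a
  tangent function for D with a vertical asymptote near stall.
* ``piecewise_linear`` -- two-segment linear fits with a knot at 5 pN nm,
  built without imposing the stall/melting anchors.
* ``hybrid_left`` / ``hybrid_right`` -- the piecewise-linear set with the
  nonlinear pause duration spliced in below / above the 5 pN nm knot.
* ``stall_family`` -- the nonlinear V and D with a pause-frequency fit whose
  value at stall torque is a chosen ``f_stall`` <= 1.
* ``tasep_constant`` -- all three responses frozen at their zero-torque
  values, which reduces the simulator to a TASEP with constant-rate pauses.

Because the measurements were taken on a template transcribed at ~22 nt/s
while rrn operons are transcribed at ~90 nt/s, the velocity (only) is scaled
by ``K = beta / V(0)`` so that a torque-free polymerase moves at ``beta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "ResponseSet",
    "VARIANTS",
    "STALL_TORQUE",
    "velocity_nonlinear",
    "pause_frequency_nonlinear",
    "pause_duration_nonlinear",
    "velocity_piecewise_linear",
    "pause_frequency_piecewise_linear",
    "pause_duration_piecewise_linear",
    "responses_piecewise_linear",
    "build_stall_family",
    "make_response_set",
    "wang_force_velocity",
]

#: average stall torque in pN nm; anchor point of the response fits
STALL_TORQUE = 11.0

#: torque value at which the pause-duration tangent diverges
PAUSE_DURATION_ASYMPTOTE = (math.pi / 2 - 0.1469) * 23.0 / math.pi

#: melting torque in pN nm; DNA denatures at stronger assisting torque
MELTING_TORQUE = -10.0

VARIANTS = (
    "nonlinear",
    "piecewise_linear",
    "hybrid_left",
    "hybrid_right",
    "stall_family",
    "tasep_constant",
)


def velocity_nonlinear(tau: float) -> float:
    """Fifth-order polynomial velocity fit, nt/s, floored at zero.

    Anchored at V(-10) = 45 nt/s (strong assisting torque roughly doubles the
    zero-torque velocity of 22.36 nt/s) and decaying toward stall.
    """
    v = (
        ((((-0.0002 * tau + 0.0008) * tau + 0.0041) * tau - 0.035) * tau - 0.2166)
        * tau
        + 22.3574
    )
    return v if v > 0.0 else 0.0


def pause_frequency_nonlinear(tau: float) -> float:
    """Piecewise-quadratic pause probability per step, clipped to [0, 1].

    A single quadratic fits the data up to 7.5 pN nm; a second quadratic
    carries the curve up to probability 1 at the stall torque.
    """
    if tau <= 7.5:
        f = (0.0001 * tau + 0.0022) * tau + 0.0128
    else:
        f = (0.0453 * tau - 0.5621) * tau + 1.7032
    if f < 0.0:
        return 0.0
    return f if f < 1.0 else 1.0


def pause_duration_nonlinear(tau: float) -> float:
    """Tangent pause-duration fit in seconds, floored at zero.

    Diverges at tau* ~ 10.42 pN nm, capturing indefinite pausing at stall;
    callers must clamp torque below tau* (the default +-10 clamp does).  At
    the melting torque the fit's anchor is an imposed duration of exactly
    zero -- a pause under that much assisting torque releases immediately --
    so the residual ~7 ms the raw tangent would give there is zeroed.
    """
    if tau >= PAUSE_DURATION_ASYMPTOTE:
        raise ValueError(
            f"pause duration undefined at tau={tau}: at or beyond the "
            f"asymptote {PAUSE_DURATION_ASYMPTOTE:.4f} pN nm"
        )
    if tau <= MELTING_TORQUE:
        return 0.0
    d = 0.1914 * math.tan((math.pi / 23.0) * tau + 0.1469) + 0.5298
    return d if d > 0.0 else 0.0


def velocity_piecewise_linear(tau: float) -> float:
    """Two-segment linear velocity fit (knot at 5 pN nm), nt/s, floored at 0."""
    v = -0.2727 * tau + 22.3636 if tau <= 5.0 else -1.2 * tau + 27.0
    return v if v > 0.0 else 0.0


def pause_frequency_piecewise_linear(tau: float) -> float:
    """Two-segment linear pause probability, clipped to [0, 1]."""
    f = 0.002277 * tau + 0.013864 if tau <= 5.0 else 0.004 * tau + 0.005
    if f < 0.0:
        return 0.0
    return f if f < 1.0 else 1.0


def pause_duration_piecewise_linear(tau: float) -> float:
    """Two-segment linear pause duration in seconds, floored at zero."""
    d = 0.027273 * tau + 0.563636 if tau <= 5.0 else 0.12 * tau + 0.1
    return d if d > 0.0 else 0.0


def responses_piecewise_linear(tau: float) -> tuple[float, float, float]:
    """Evaluate the piecewise-linear (V, F, D) triple at one torque value."""
    return (
        velocity_piecewise_linear(tau),
        pause_frequency_piecewise_linear(tau),
        pause_duration_piecewise_linear(tau),
    )


def wang_force_velocity(f: float, a: float = 1.0) -> float:
    """Normalized force-velocity curve of a molecular motor (reference only).

    ``V(f) ~ 1 / (1 + a^(f-1))`` for dimensionless assisting/resisting force
    ``f``, extended antisymmetrically to negative forces.  This is the
    theoretically motivated shape that justifies approximating the velocity
    response with a low-order polynomial; it is documented here for
    comparison and is never called by the simulator.
    """
    if f < 0.0:
        return -wang_force_velocity(-f, a)
    return 1.0 / (1.0 + a ** (f - 1.0))


@dataclass(frozen=True)
class ResponseSet:
    """The (V, F, D) triple plus the velocity scale factor K.

    ``K * velocity_fn(0) == beta_target`` so that an unperturbed polymerase
    elongates at ``beta_target`` nt/s.  Pause durations are *not* rescaled by
    K; the measured durations are used as-is.
    """

    variant: str
    velocity_fn: Callable[[float], float]
    pause_freq_fn: Callable[[float], float]
    pause_dur_fn: Callable[[float], float]
    scale_K: float
    beta_target: float
    f_stall: float | None = None

    def __post_init__(self) -> None:
        v0 = self.velocity_fn(0.0)
        if abs(self.scale_K * v0 - self.beta_target) > 1e-9 * self.beta_target:
            raise ValueError("scale_K * V(0) must equal beta_target")


def build_stall_family(f_stall: float, beta_target: float = 90.0) -> ResponseSet:
    """Pause-frequency family with a chosen value ``f_stall`` at stall torque.

    Keeps the nonlinear V and D and the first quadratic branch of F below
    7.5 pN nm; above the knot, the unique quadratic matching the first
    branch's value and slope at 7.5 and passing through (11, f_stall)
    replaces the stall branch.  ``f_stall = 1`` recovers the stall anchor of
    the standard nonlinear fit at the endpoints; ``f_stall ~ 0.05`` is
    essentially the single-quadratic fit extended over the whole range.
    """
    if not 0.0 < f_stall <= 1.0:
        raise ValueError("f_stall must lie in (0, 1]")
    knot = 7.5
    f_knot = pause_frequency_nonlinear(knot)
    slope_knot = 2 * 0.0001 * knot + 0.0022
    # aquad (tau-knot)^2 + slope_knot (tau-knot) + f_knot through (11, f_stall)
    span = STALL_TORQUE - knot
    aquad = (f_stall - f_knot - slope_knot * span) / span**2

    def pause_freq(tau: float, _a=aquad, _k=knot, _f=f_knot, _s=slope_knot) -> float:
        if tau <= _k:
            f = (0.0001 * tau + 0.0022) * tau + 0.0128
        else:
            dt = tau - _k
            f = (_a * dt + _s) * dt + _f
        if f < 0.0:
            return 0.0
        return f if f < 1.0 else 1.0

    return ResponseSet(
        variant="stall_family",
        velocity_fn=velocity_nonlinear,
        pause_freq_fn=pause_freq,
        pause_dur_fn=pause_duration_nonlinear,
        scale_K=beta_target / velocity_nonlinear(0.0),
        beta_target=beta_target,
        f_stall=f_stall,
    )


def _hybrid_duration(side: str) -> Callable[[float], float]:
    """Pause duration splicing nonlinear and piecewise-linear fits at 5 pN nm."""

    def left(tau: float) -> float:  # nonlinear below the knot
        if tau <= 5.0:
            return pause_duration_nonlinear(tau)
        return pause_duration_piecewise_linear(tau)

    def right(tau: float) -> float:  # nonlinear above the knot
        if tau <= 5.0:
            return pause_duration_piecewise_linear(tau)
        return pause_duration_nonlinear(tau)

    return left if side == "left" else right


def make_response_set(
    variant: str,
    beta_target: float = 90.0,
    f_stall: float | None = None,
) -> ResponseSet:
    """Package one response variant with its velocity scale factor.

    ``tasep_constant`` freezes the nonlinear fit at zero torque: the
    simulator then runs a plain TASEP with elongation rate ``beta_target``,
    constant pause probability F(0) and constant pause duration D(0).
    """
    if beta_target <= 0:
        raise ValueError("beta_target must be positive")
    if variant == "stall_family":
        if f_stall is None:
            raise ValueError("stall_family requires f_stall")
        return build_stall_family(f_stall, beta_target)
    if f_stall is not None:
        raise ValueError("f_stall only applies to the stall_family variant")

    if variant == "nonlinear":
        vfn, ffn, dfn = (
            velocity_nonlinear,
            pause_frequency_nonlinear,
            pause_duration_nonlinear,
        )
    elif variant == "piecewise_linear":
        vfn, ffn, dfn = (
            velocity_piecewise_linear,
            pause_frequency_piecewise_linear,
            pause_duration_piecewise_linear,
        )
    elif variant in ("hybrid_left", "hybrid_right"):
        vfn = velocity_piecewise_linear
        ffn = pause_frequency_piecewise_linear
        dfn = _hybrid_duration(variant.removeprefix("hybrid_"))
    elif variant == "tasep_constant":
        v0 = velocity_nonlinear(0.0)
        f0 = pause_frequency_nonlinear(0.0)
        d0 = pause_duration_nonlinear(0.0)
        vfn = lambda tau, _v=v0: _v  # noqa: E731
        ffn = lambda tau, _f=f0: _f  # noqa: E731
        dfn = lambda tau, _d=d0: _d  # noqa: E731
    else:
        raise ValueError(f"unknown response variant {variant!r}")

    v0 = vfn(0.0)
    if v0 <= 0:
        raise ValueError("zero-torque velocity must be positive")
    return ResponseSet(
        variant=variant,
        velocity_fn=vfn,
        pause_freq_fn=ffn,
        pause_dur_fn=dfn,
        scale_K=beta_target / v0,
        beta_target=beta_target,
    )


def tabulate(responses: ResponseSet, taus: np.ndarray) -> np.ndarray:
    """Evaluate (tau, K*V, F, D) over an array of torques, for plotting/tables."""
    out = np.empty((len(taus), 4))
    for i, tau in enumerate(np.asarray(taus, dtype=float)):
        out[i] = (
            tau,
            responses.scale_K * responses.velocity_fn(tau),
            responses.pause_freq_fn(tau),
            responses.pause_dur_fn(tau),
        )
    return out
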