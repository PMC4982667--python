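"""Elastic-rod torque between neighboring RNA polymerases.

The stretch of double-stranded DNA between the transcription bubbles of two
adjacent polymerases is short relative to the bend-persistence length of DNA
(~150 bp), so it behaves like an elastic rod.  When one polymerase
translocates without rotating, the helical repeat (10.5 bp/turn) forces a
twist into that rod; the accumulated twist exerts a torque on both anchoring
polymerases.  For a rod shortened from its relaxed length ``L0`` to ``L`` the
stored torque integrates to

    tau(L) = (mu * pi^2 * r^4 / pitch) * ln(L0 / L)

with shear modulus ``mu``, rod radius ``r`` and helical pitch expressed in
the chosen length unit.  Over-twist (``L < L0``) gives positive, resisting
torque ahead of a mover; under-twist gives negative, assisting torque.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ElasticConstants",
    "TorqueModel",
    "derive_elastic_constants",
    "segment_torque",
    "net_torque",
    "bubble_gap",
    "HELIX_PITCH_BP",
    "BP_TO_NM",
]

#: base pairs per full helical turn of B-form DNA
HELIX_PITCH_BP = 10.5
#: rise per base pair in nanometers
BP_TO_NM = 0.34


@dataclass(frozen=True)
class ElasticConstants:
    """Material parameters of the DNA rod and the derived torque prefactor.

    Units: ``young_modulus`` and ``shear_modulus`` in pN/nm^2, ``bending_modulus``
    and ``twisting_modulus`` in pN nm^2, ``rod_radius`` in nm,
    ``torque_prefactor`` in pN nm.
    """

    young_modulus: float
    bending_modulus: float
    twisting_modulus: float
    rod_radius: float
    poisson_ratio: float
    shear_modulus: float
    torque_prefactor: float
    length_convention: str = "nm"
    helix_pitch_bp: float = HELIX_PITCH_BP
    bp_to_nm: float = BP_TO_NM


def derive_elastic_constants(
    young_modulus: float = 300.0,
    bending_modulus: float = 230.0,
    twisting_modulus: float = 460.0,
    rod_radius: float = 1.0,
    length_convention: str = "nm",
) -> ElasticConstants:
    """Derive Poisson ratio, shear modulus and the torque prefactor.

    The Poisson ratio follows from the bending/twisting moduli,
    ``nu = B/C - 1``, and the shear modulus from ``mu = Y / (2 (1 + nu))``.
    The prefactor multiplying ``ln(L0/L)`` is ``mu pi^2 r^4 / pitch`` where the
    pitch is 10.5 bp expressed either in nanometers (``10.5 * 0.34``, the
    default) or left in base pairs (``length_convention="bp"``).

    Defaults are the standard DNA values: Y = 300 pN/nm^2 (300 MPa),
    B = 230 pN nm^2, C = 460 pN nm^2, r = 1 nm, giving nu = -0.5 and
    mu = 300 pN/nm^2.
    """
    if twisting_modulus == 0:
        raise ValueError("twisting modulus must be nonzero")
    nu = bending_modulus / twisting_modulus - 1.0
    if nu == -1.0:
        raise ValueError("Poisson ratio of -1 leaves the shear modulus undefined")
    mu = young_modulus / (2.0 * (1.0 + nu))
    if length_convention == "nm":
        pitch = HELIX_PITCH_BP * BP_TO_NM
    elif length_convention == "bp":
        pitch = HELIX_PITCH_BP
    else:
        raise ValueError(f"unknown length convention {length_convention!r}")
    prefactor = mu * math.pi**2 * rod_radius**4 / pitch
    return ElasticConstants(
        young_modulus=young_modulus,
        bending_modulus=bending_modulus,
        twisting_modulus=twisting_modulus,
        rod_radius=rod_radius,
        poisson_ratio=nu,
        shear_modulus=mu,
        torque_prefactor=prefactor,
        length_convention=length_convention,
    )


@dataclass(frozen=True)
class TorqueModel:
    """Torque prefactor plus the clamp applied to the net torque.

    ``clamp_high`` defaults to +10 pN nm, just below the average stall torque
    of ~11 pN nm and below the vertical asymptote of the pause-duration fit
    (~10.42 pN nm); ``clamp_low`` defaults to the DNA melting torque of
    -10 pN nm.  Clamping the net torque keeps all three response functions
    finite and positive.

    With ``clamp_segments`` the torque stored in each DNA segment is itself
    bounded by the same interval before the two sides are combined, so a
    polymerase squeezed symmetrically from both sides experiences a small
    net torque.  By default only the combined torque is clamped, which
    reproduces the observed torque-value distribution (heavy mass at both
    clamp values) in dense traffic.
    """

    constants: ElasticConstants = field(default_factory=derive_elastic_constants)
    clamp_low: float = -10.0
    clamp_high: float = 10.0
    clamp_segments: bool = False

    def __post_init__(self) -> None:
        if not self.clamp_low < 0.0 < self.clamp_high:
            raise ValueError("clamp interval must straddle zero")

    @property
    def length_convention(self) -> str:
        return self.constants.length_convention


def segment_torque(model: TorqueModel, L0: float, L: float) -> float:
    """Torque stored in one inter-polymerase DNA segment, in pN nm.

    ``L0`` is the bubble-to-bubble distance at the trailing polymerase's
    initiation and ``L`` the current distance, both in nucleotides.  The
    result is positive for an over-twisted (shortened) segment and negative
    for an under-twisted one; it is antisymmetric in ``(L0, L)`` and additive
    along chained length changes because of the logarithm.  When the model
    clamps segment torques, values beyond the melting/stall bounds are
    truncated to them.
    """
    if L <= 0 or L0 <= 0:
        raise ValueError("segment lengths must be positive")
    tau = model.constants.torque_prefactor * math.log(L0 / L)
    if model.clamp_segments:
        if tau > model.clamp_high:
            return model.clamp_high
        if tau < model.clamp_low:
            return model.clamp_low
    return tau


def net_torque(
    model: TorqueModel,
    tau_front: float | None,
    tau_back: float | None,
) -> float:
    """Net torque on a polymerase from its two flanking segments, clamped.

    The front segment resists with ``+tau_front`` while the back segment
    contributes ``-tau_back`` (over-twist behind pushes the polymerase
    forward).  An absent neighbor contributes zero on its side.  The result
    is clamped to ``[clamp_low, clamp_high]`` before any response-function
    lookup.
    """
    tau = (tau_front or 0.0) - (tau_back or 0.0)
    if tau > model.clamp_high:
        return model.clamp_high
    if tau < model.clamp_low:
        return model.clamp_low
    return tau


def bubble_gap(
    n_leader: int, n_self: int, bubble_len: int = 17, footprint: int = 35
) -> int:
    """Distance in nucleotides between the transcription bubbles of two RNAPs.

    Positions are the furthest-downstream nucleotide of each footprint.  The
    17-nt bubble of the leader is anchored and cannot twist, so it is
    subtracted from the front-to-front distance; with a 35-nt footprint the
    minimum gap between bubbles of touching polymerases is 18 nt.
    """
    if n_leader <= n_self:
        raise ValueError("leader must be downstream of the trailing polymerase")
    if n_leader - n_self < footprint:
        raise ValueError(
            f"polymerases overlap: front positions {n_leader} and {n_self} "
            f"are closer than one footprint ({footprint} nt)"
        )
    return (n_leader - n_self) - bubble_len
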