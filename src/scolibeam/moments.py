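"""Apex bending moments of axial and lateral corrective loads versus the
Cobb angle.

In a three-point correction scheme the lateral load acts at the curve apex
C and is reacted at the end vertebrae A and B (each carrying half of it),
while the axial traction acts along the chord AB. With chord length d and
Cobb angle theta, the apex bending moments are

    M_P = P (d/2) sin(theta/2)        (axial traction)
    M_Q = (Q/2)(d/2) cos(theta/2)     (lateral three-point load)

M_P grows and M_Q shrinks with the Cobb angle, so each load dominates on
one side of a crossover angle theta* = 2 arctan(Q / (2P)) — independent of
d. At equal load magnitudes theta* = 2 arctan(1/2) ~= 53.13 deg: lateral
correction is the more effective lever for milder curves, axial traction
for more severe ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ScolibeamError
from .geometry import PolynomialProfile, profile_derivatives

__all__ = [
    "CobbGeometry",
    "MomentComparison",
    "axial_moment",
    "lateral_moment",
    "crossover_angle",
    "dominant_load",
    "cobb_from_profile",
]

_EQUAL_TOL = 1e-12  # N·m


@dataclass(frozen=True)
class CobbGeometry:
    """Cobb angle theta (degrees) and chord distance d (m) between the
    end-vertebra load points A and B."""

    theta_deg: float
    d: float

    def __post_init__(self):
        if not 0.0 <= self.theta_deg < 180.0:
            raise ScolibeamError("Cobb angle must lie in [0, 180) degrees")
        if self.d <= 0:
            raise ScolibeamError("chord distance d must be positive")


@dataclass(frozen=True)
class MomentComparison:
    """Apex moments of the two loads and which dominates."""

    M_P: float
    M_Q: float
    dominant: str  # "axial" | "lateral" | "equal"


def axial_moment(P: float, geom: CobbGeometry) -> float:
    """Apex bending moment of the axial traction, P (d/2) sin(theta/2)."""
    return P * (geom.d / 2.0) * math.sin(math.radians(geom.theta_deg) / 2.0)


def lateral_moment(Q: float, geom: CobbGeometry) -> float:
    """Apex bending moment of the lateral load, (Q/2)(d/2) cos(theta/2)."""
    return (Q / 2.0) * (geom.d / 2.0) * math.cos(math.radians(geom.theta_deg) / 2.0)


def crossover_angle(P: float = 1.0, Q: float = 1.0) -> float:
    """Cobb angle (degrees) at which the two apex moments are equal:
    2 arctan(Q / (2P)); independent of the chord distance d.

    The default equal-magnitude loads give 2 arctan(1/2) ~= 53.13 deg.
    """
    if P <= 0:
        raise ScolibeamError("axial load P must be positive")
    if Q < 0:
        raise ScolibeamError("lateral load Q must be non-negative")
    return math.degrees(2.0 * math.atan(Q / (2.0 * P)))


def dominant_load(P: float, Q: float, geom: CobbGeometry) -> MomentComparison:
    """Compare the two apex moments at the given Cobb geometry."""
    mp = axial_moment(P, geom)
    mq = lateral_moment(Q, geom)
    if abs(mq - mp) <= _EQUAL_TOL:
        dom = "equal"
    elif mq > mp:
        dom = "lateral"
    else:
        dom = "axial"
    return MomentComparison(M_P=mp, M_Q=mq, dominant=dom)


def cobb_from_profile(profile: PolynomialProfile, h: float) -> float:
    """Tangent-based Cobb-angle estimate (degrees) from the fitted profile:
    |arctan y0'(-h)| + |arctan y0'(+h)|, the angle between the end tangents.

    A convenience for synthetic studies — clinically the Cobb angle is
    measured on standing radiographs from vertebral endplates, which this
    geometric estimate does not replace.
    """
    s_lo = profile_derivatives(profile, -h, 1)
    s_hi = profile_derivatives(profile, h, 1)
    return math.degrees(abs(math.atan(s_lo)) + abs(math.atan(s_hi)))
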