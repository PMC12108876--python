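"""Traction-load planning: inverting the beam model for required loads.

Given the fitted initial profile and the beam constants, find the total
axial traction P at which the residual lateral displacement at a chosen
station vanishes, convert body-weight fractions and traction angles into
loads, estimate the number of treatment sessions needed to accumulate the
required total, and trace the trade-off between axial and lateral loads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .beam import BeamParameters, LoadCase, solve_closed_form
from .errors import ScolibeamError, TargetUnreachableError
from .geometry import PolynomialProfile

__all__ = [
    "PlanningTarget",
    "TradeoffCurve",
    "DEFAULT_BRACKET",
    "required_axial_load",
    "total_load_at_angle",
    "load_from_body_weight",
    "sessions_required",
    "tradeoff_curve",
]

DEFAULT_BRACKET = (1.0, 1.0e6)

#: Default station (m) at which correction is assessed for the reference
#: patient: near the superior end, where the residual displacement first
#: crosses zero as the load grows. The curve apex (x = 0.035 m for the
#: reference patient) is an alternative; both are supported.
DEFAULT_STATION = 0.095


@dataclass(frozen=True)
class PlanningTarget:
    """Correction objective: drive y(station) to ``target_displacement``."""

    station: float = DEFAULT_STATION
    target_displacement: float = 0.0


@dataclass(frozen=True)
class TradeoffCurve:
    """Required axial load as a function of the lateral corrective load.

    Entries are (Q, P_required) with Q strictly increasing and P_required
    strictly decreasing — adding lateral correction always reduces the
    axial traction needed.
    """

    entries: tuple[tuple[float, float], ...]

    def __post_init__(self):
        Qs = [q for q, _ in self.entries]
        Ps = [p for _, p in self.entries]
        if any(b <= a for a, b in zip(Qs, Qs[1:])):
            raise ScolibeamError("trade-off entries must have strictly increasing Q")
        if any(b >= a for a, b in zip(Ps, Ps[1:])):
            raise ScolibeamError(
                "trade-off entries must have strictly decreasing required P"
            )

    def as_dict(self) -> list[dict]:
        return [{"Q_N": q, "P_required_N": p} for q, p in self.entries]


def _residual_factory(profile, params, Q, target):
    def residual(P: float) -> float:
        sol = solve_closed_form(profile, params, LoadCase(P=P, Q=Q))
        return sol.total(target.station) - target.target_displacement

    return residual


def required_axial_load(
    profile: PolynomialProfile,
    params: BeamParameters,
    Q: float = 0.0,
    target: PlanningTarget = PlanningTarget(),
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    tol_N: float = 0.5,
) -> float:
    """Smallest axial load P in ``bracket`` driving y(station) to target.

    A coarse geometric scan locates the first sign change of
    P -> y(station; P, Q) - target, then Brent's method refines the root
    to ``tol_N`` (0.5 N by default — finer precision has no physical
    meaning here). Raises :class:`TargetUnreachableError`, reporting the
    endpoint displacements, when the bracket contains no sign change.
    """
    if not -params.h < target.station < params.h:
        raise ScolibeamError("planning station must lie strictly inside (-h, h)")
    lo, hi = bracket
    residual = _residual_factory(profile, params, Q, target)
    Ps = np.geomspace(lo, hi, 256)
    vals = np.array([residual(P) for P in Ps])
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) <= 0)[0]
    if sign_change.size == 0:
        raise TargetUnreachableError(
            f"target unreachable in bracket ({lo}, {hi}) N: "
            f"y - target = {vals[0]:.3e} m at P = {lo} N and "
            f"{vals[-1]:.3e} m at P = {hi} N"
        )
    i = int(sign_change[0])  # first crossing -> smallest positive root
    return float(brentq(residual, Ps[i], Ps[i + 1], xtol=tol_N))


def total_load_at_angle(P_axial: float, alpha_deg: float) -> float:
    """Total traction load whose axial component equals ``P_axial`` when
    pulled at ``alpha_deg`` from the spine axis: P_axial / cos(alpha)."""
    if not 0.0 <= alpha_deg < 90.0:
        raise ScolibeamError("traction angle must lie in [0, 90) degrees")
    return P_axial / math.cos(math.radians(alpha_deg))


def load_from_body_weight(mass_kg: float, fraction: float, g: float = 10.0) -> float:
    """Load (N) as a fraction of body weight.

    g defaults to 10 m/s², the rounding used in the reference treatment
    protocol (0.40 x 65 kg x 10 = 260 N exactly).
    """
    if mass_kg <= 0:
        raise ScolibeamError("mass must be positive")
    if not 0.0 <= fraction <= 1.0:
        raise ScolibeamError("fraction must lie in [0, 1]")
    return fraction * mass_kg * g


def sessions_required(P_total: float, per_session: float) -> int:
    """Number of sessions for the cumulative applied load to reach
    ``P_total`` at ``per_session`` newtons each: ceil(P_total / per_session)."""
    if per_session <= 0:
        raise ScolibeamError("per-session load must be positive")
    if P_total < 0:
        raise ScolibeamError("total load must be non-negative")
    return math.ceil(P_total / per_session)


def tradeoff_curve(
    profile: PolynomialProfile,
    params: BeamParameters,
    target: PlanningTarget = PlanningTarget(),
    Q_grid=(0.0, 40.0, 80.0, 120.0, 162.5),
    bracket: tuple[float, float] = DEFAULT_BRACKET,
) -> TradeoffCurve:
    """Required axial load for each lateral load in ``Q_grid``."""
    entries = []
    for Q in Q_grid:
        try:
            P = required_axial_load(profile, params, Q=Q, target=target, bracket=bracket)
        except ScolibeamError as exc:
            raise TargetUnreachableError(f"at Q = {Q} N: {exc}") from exc
        entries.append((float(Q), P))
    return TradeoffCurve(entries=tuple(entries))
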