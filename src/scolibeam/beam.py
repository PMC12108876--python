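"""Tension beam-column model of the loaded scoliotic spine.

The scoliotic curve is idealised as an initially bent beam-column of
bending stiffness EI spanning x in [-h, +h]. Under an axial traction load
P (effective axial component P_eff = P cos(alpha)) and a uniformly
distributed lateral corrective load Q, the correction-induced displacement
y1 obeys

    EI y1'''' - P_eff y1'' = -Q + P_eff y0''

with pinned, zero-moment ends by default:

    y1(+-h) = 0,   y1''(+-h) = 0.

Because the axial load is tensile, the homogeneous solutions are
exponential (cosh/sinh with rate k = sqrt(P_eff/EI)) rather than
oscillatory, and increasing P always pulls the total displacement
y = y0 + y1 toward zero. For a cubic initial profile y0 the particular
solution is -y0 + Q x^2 / (2 P_eff), which yields the closed form

    y(x) = c0 + c1 x + c_cosh cosh(kx) + c_sinh sinh(kx) + Q x^2 / (2 P_eff).

An optional boundary-condition mode models the end restraints as
rotational springs (end moment proportional to end slope, with stiffnesses
ks at the inferior end and ki = 3 EI / Li at the superior end); it is off
by default and provided for sensitivity studies only.

:func:`solve_bvp_numeric` solves the same boundary-value problem by
second-order central finite differences and serves as an independent check
on the closed form; it also covers the degenerate pure-lateral case
P_eff = 0 and spatially varying Q(x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .errors import BeamModelError, DegenerateLoadError
from .geometry import PolynomialProfile, profile_derivatives

__all__ = [
    "BeamParameters",
    "LoadCase",
    "DisplacementSolution",
    "effective_axial_load",
    "solve_closed_form",
    "solve_bvp_numeric",
    "total_displacement",
]

# cosh overflows double precision near k*h ~ 710; stay well below.
_MAX_KH = 350.0


@dataclass(frozen=True)
class BeamParameters:
    """Structural constants of the spine segment.

    EI : bending stiffness, N·m² (15.1 for the reference patient, from
        cadaveric lumbar bending experiments).
    L : length of the scoliotic curve, m.
    Li : length of spine inferior to the curve, m; sets the superior-end
        rotational spring ki = 3 EI / Li used by the optional spring
        boundary mode.
    ks : inferior-end rotational spring constant, N·m/rad (0 = free).
    """

    EI: float
    L: float
    Li: float = 0.0
    ks: float = 0.0
    ki: float = field(init=False)

    def __post_init__(self):
        if self.EI <= 0:
            raise BeamModelError("EI must be positive")
        if self.L <= 0:
            raise BeamModelError("L must be positive")
        if self.ks < 0 or self.Li < 0:
            raise BeamModelError("spring constants and Li must be non-negative")
        ki = 3.0 * self.EI / self.Li if self.Li > 0 else 0.0
        object.__setattr__(self, "ki", ki)

    @property
    def h(self) -> float:
        """Half-length of the curve, m."""
        return self.L / 2.0


@dataclass(frozen=True)
class LoadCase:
    """Applied loads: total axial traction P (N) at angle alpha (degrees)
    from the spine axis, and uniform lateral corrective load Q (N)."""

    P: float = 0.0
    Q: float = 0.0
    alpha_deg: float = 0.0

    def __post_init__(self):
        if self.P < 0 or self.Q < 0:
            raise BeamModelError("loads must be non-negative")
        if not (0.0 <= self.alpha_deg < 90.0):
            raise BeamModelError("traction angle must lie in [0, 90) degrees")


def effective_axial_load(load: LoadCase) -> float:
    """Axial component of the traction load, P cos(alpha), in N."""
    return load.P * math.cos(math.radians(load.alpha_deg))


@dataclass(frozen=True)
class DisplacementSolution:
    """Total lateral displacement y(x) = y0(x) + y1(x) of the loaded beam.

    Closed-form solutions carry the coefficients of

        y(x) = c0 + c1 x + c_cosh cosh(kx) + c_sinh sinh(kx) + q_quad x^2;

    grid-backed (finite-difference) solutions carry the node values of y1
    and interpolate linearly between nodes. ``total`` and ``correction``
    evaluate y and y1 with a domain check on [-h, +h].
    """

    profile: PolynomialProfile
    h: float
    P_eff: float
    Q: float
    k: float | None = None
    c0: float | None = None
    c1: float | None = None
    c_cosh: float | None = None
    c_sinh: float | None = None
    q_quad: float | None = None
    grid_x: np.ndarray | None = None
    grid_y1: np.ndarray | None = None

    @property
    def is_closed_form(self) -> bool:
        return self.c0 is not None

    def _check_domain(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < -self.h - 1e-12) or np.any(x > self.h + 1e-12):
            raise BeamModelError(f"station outside [-h, h] = [{-self.h}, {self.h}]")
        return x

    def total(self, x):
        """y(x) = y0(x) + y1(x), in m."""
        x = self._check_domain(x)
        if self.is_closed_form:
            val = (
                self.c0
                + self.c1 * x
                + self.c_cosh * np.cosh(self.k * x)
                + self.c_sinh * np.sinh(self.k * x)
                + self.q_quad * x**2
            )
        else:
            val = profile_derivatives(self.profile, x, 0) + np.interp(
                x, self.grid_x, self.grid_y1
            )
        return float(val) if np.ndim(x) == 0 else val

    def correction(self, x):
        """Load-induced displacement y1(x), in m."""
        x = self._check_domain(x)
        if self.is_closed_form:
            val = self.total(x) - profile_derivatives(self.profile, x, 0)
        else:
            val = np.interp(x, self.grid_x, self.grid_y1)
        return float(val) if np.ndim(x) == 0 else val

    def correction_curvature(self, x):
        """Analytic y1''(x) for closed-form solutions, in 1/m."""
        if not self.is_closed_form:
            raise BeamModelError("analytic curvature requires a closed-form solution")
        x = self._check_domain(x)
        k = self.k
        ypp = (
            k * k * (self.c_cosh * np.cosh(k * x) + self.c_sinh * np.sinh(k * x))
            + 2.0 * self.q_quad
            - profile_derivatives(self.profile, x, 2)
        )
        return float(ypp) if np.ndim(x) == 0 else ypp

    def sample(self, n: int = 201) -> dict:
        """JSON-ready report with coefficients and an (x, y) table."""
        xs = np.linspace(-self.h, self.h, n)
        out = {
            "P_eff_N": self.P_eff,
            "Q_N": self.Q,
            "k_per_m": self.k,
            "coefficients": None,
            "x_m": xs.tolist(),
            "y_m": np.asarray(self.total(xs)).tolist(),
        }
        if self.is_closed_form:
            out["coefficients"] = {
                "c0": self.c0,
                "c1": self.c1,
                "c_cosh": self.c_cosh,
                "c_sinh": self.c_sinh,
                "q_quad": self.q_quad,
            }
        return out


def _particular(profile: PolynomialProfile, P_eff: float, Q: float):
    """Particular solution y1p = -y0 + Q x^2/(2 P_eff) and derivatives.

    Valid because y0 is at most cubic, so y0'''' = 0.
    """

    def p(x, order):
        base = -profile_derivatives(profile, x, order)
        if order == 0:
            base = base + Q * x * x / (2.0 * P_eff)
        elif order == 1:
            base = base + Q * x / P_eff
        elif order == 2:
            base = base + Q / P_eff
        return base

    return p


def solve_closed_form(
    profile: PolynomialProfile,
    params: BeamParameters,
    load: LoadCase,
    spring_bc: bool = False,
) -> DisplacementSolution:
    """Solve the tension beam-column equation in closed form.

    The homogeneous part C1 + C2 x + C3 cosh(kx) + C4 sinh(kx) with
    k = sqrt(P_eff/EI) is combined with the particular solution
    -y0 + Q x^2/(2 P_eff); the four constants are fixed by the boundary
    conditions (zero displacement at both ends, plus either zero end
    moment — the default — or the rotational-spring end-moment relations
    when ``spring_bc`` is set).
    """
    if profile.degree > 3:
        raise BeamModelError(
            "closed form requires a profile of degree <= 3 (y0'''' must vanish); "
            "use solve_bvp_numeric for higher degrees"
        )
    P_eff = effective_axial_load(load)
    if P_eff <= 0.0:
        raise DegenerateLoadError(
            "effective axial load is zero: the equation degenerates to pure "
            "lateral bending; use solve_bvp_numeric"
        )
    EI, h = params.EI, params.h
    k = math.sqrt(P_eff / EI)
    if k * h > _MAX_KH:
        raise BeamModelError(f"k*h = {k * h:.3g} exceeds overflow guard {_MAX_KH}")
    Q = load.Q
    p = _particular(profile, P_eff, Q)

    ch, sh = math.cosh(k * h), math.sinh(k * h)
    # unknowns C = [C1, C2, C3, C4]; y1 = C1 + C2 x + C3 cosh + C4 sinh + y1p
    A = np.zeros((4, 4))
    b = np.zeros(4)
    A[0] = [1.0, -h, ch, -sh]
    b[0] = -p(-h, 0)
    A[1] = [1.0, h, ch, sh]
    b[1] = -p(h, 0)
    if not spring_bc:
        # zero end moment: y1''(+-h) = 0
        A[2] = [0.0, 0.0, k * k * ch, -k * k * sh]
        b[2] = -p(-h, 2)
        A[3] = [0.0, 0.0, k * k * ch, k * k * sh]
        b[3] = -p(h, 2)
    else:
        # EI y1'' = ks y1' at -h ; -EI y1'' = ki y1' at +h
        ks, ki = params.ks, params.ki
        A[2] = [
            0.0,
            -ks,
            EI * k * k * ch + ks * k * sh,
            -EI * k * k * sh - ks * k * ch,
        ]
        b[2] = -(EI * p(-h, 2) - ks * p(-h, 1))
        A[3] = [
            0.0,
            -ki,
            -EI * k * k * ch - ki * k * sh,
            -EI * k * k * sh - ki * k * ch,
        ]
        b[3] = EI * p(h, 2) + ki * p(h, 1)
    C1, C2, C3, C4 = np.linalg.solve(A, b)

    # the particular part -y0 cancels against y0 in y = y0 + y1, leaving
    # the homogeneous constants plus the Q x^2/(2 P_eff) term
    return DisplacementSolution(
        profile=profile,
        h=h,
        P_eff=P_eff,
        Q=Q,
        k=k,
        c0=float(C1),
        c1=float(C2),
        c_cosh=float(C3),
        c_sinh=float(C4),
        q_quad=Q / (2.0 * P_eff),
    )


def solve_bvp_numeric(
    profile: PolynomialProfile,
    params: BeamParameters,
    load: LoadCase,
    n_nodes: int = 2001,
    Q_func: Callable | None = None,
    spring_bc: bool = False,
) -> DisplacementSolution:
    """Finite-difference solution of the same boundary-value problem.

    Second-order central differences on a uniform grid over [-h, +h];
    the two end-moment (or spring) conditions are imposed with one-sided
    second-order stencils. ``Q_func`` optionally replaces the uniform
    lateral load with an intensity profile Q(x). Independent of the
    closed form — used as a numerical oracle and for the P_eff = 0 and
    spatially-varying-Q cases the closed form does not cover.
    """
    if n_nodes < 201 or n_nodes % 2 == 0:
        raise BeamModelError("n_nodes must be odd and at least 201")
    EI, h = params.EI, params.h
    P_eff = effective_axial_load(load)
    x = np.linspace(-h, h, n_nodes)
    d = x[1] - x[0]
    Qx = Q_func(x) if Q_func is not None else np.full_like(x, load.Q)
    rhs_interior = -Qx + P_eff * profile_derivatives(profile, x, 2)

    A = sp.lil_matrix((n_nodes, n_nodes))
    b = np.zeros(n_nodes)
    c4 = EI / d**4
    c2 = P_eff / d**2
    for i in range(2, n_nodes - 2):
        A[i, i - 2] += c4
        A[i, i - 1] += -4.0 * c4
        A[i, i] += 6.0 * c4
        A[i, i + 1] += -4.0 * c4
        A[i, i + 2] += c4
        # - P_eff y1'' term
        A[i, i - 1] += -c2
        A[i, i] += 2.0 * c2
        A[i, i + 1] += -c2
        b[i] = rhs_interior[i]

    # pinned ends
    A[0, 0] = 1.0
    b[0] = 0.0
    A[n_nodes - 1, n_nodes - 1] = 1.0
    b[n_nodes - 1] = 0.0

    # one-sided second-order stencils at the ends
    def d2_forward(row, j0, sign=1.0, scale=1.0):
        for off, w in zip((0, 1, 2, 3), (2.0, -5.0, 4.0, -1.0)):
            A[row, j0 + sign * off] += scale * w / d**2

    def d1_forward(row, j0, sign=1.0, scale=1.0):
        for off, w in zip((0, 1, 2), (-3.0, 4.0, -1.0)):
            A[row, j0 + sign * off] += scale * sign * w / (2.0 * d)

    if not spring_bc:
        d2_forward(1, 0, sign=1)
        b[1] = 0.0
        d2_forward(n_nodes - 2, n_nodes - 1, sign=-1)
        b[n_nodes - 2] = 0.0
    else:
        # EI y1'' - ks y1' = 0 at -h
        d2_forward(1, 0, sign=1, scale=EI)
        d1_forward(1, 0, sign=1, scale=-params.ks)
        b[1] = 0.0
        # -EI y1'' - ki y1' = 0 at +h
        d2_forward(n_nodes - 2, n_nodes - 1, sign=-1, scale=-EI)
        d1_forward(n_nodes - 2, n_nodes - 1, sign=-1, scale=-params.ki)
        b[n_nodes - 2] = 0.0

    try:
        y1 = spsolve(A.tocsr(), b)
    except RuntimeError as exc:  # pragma: no cover - singular systems
        raise BeamModelError(f"finite-difference system is singular: {exc}") from exc
    if not np.all(np.isfinite(y1)):
        raise BeamModelError("finite-difference solve produced non-finite values")

    return DisplacementSolution(
        profile=profile,
        h=h,
        P_eff=P_eff,
        Q=float(load.Q),
        grid_x=x,
        grid_y1=y1,
    )


def total_displacement(solution: DisplacementSolution, x) -> float:
    """Total lateral displacement y(x) = y0(x) + y1(x), in m."""
    return solution.total(x)
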