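"""Spinal midline geometry: coordinate series, frame transforms, and the
initial lateral-displacement polynomial.

The coronal-plane midline of a scoliotic curve is sampled as (X, Y) pairs in
millimetres: X runs axially from the inferior end vertebra to the superior
end vertebra, Y is the lateral deviation from the central axis. For the beam
mechanics the series is re-expressed in a midpoint-origin frame in metres
(station x in [-h, +h] with h = L/2) and the pre-treatment deviation y0(x)
is represented as a least-squares cubic polynomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FitError, MidlineParseError, MidlineValidationError

__all__ = [
    "SpineCurve",
    "BeamFrameCurve",
    "PolynomialProfile",
    "FitResult",
    "REFERENCE_PROFILE",
    "read_midline_csv",
    "curve_length",
    "max_deviation",
    "to_beam_frame",
    "from_beam_frame",
    "fit_initial_displacement",
    "profile_derivatives",
]

MIN_POINTS = 6


@dataclass(frozen=True)
class SpineCurve:
    """An ordered midline coordinate series in the device frame (mm).

    ``X_mm`` must be strictly increasing with at least ``MIN_POINTS``
    entries; ``Y_mm`` must be finite. ``spacing_mm`` records the nominal
    sampling interval of the digitisation (7 mm for the bundled series).
    """

    X_mm: np.ndarray
    Y_mm: np.ndarray
    spacing_mm: float = 7.0

    def __post_init__(self):
        X = np.asarray(self.X_mm, dtype=float)
        Y = np.asarray(self.Y_mm, dtype=float)
        object.__setattr__(self, "X_mm", X)
        object.__setattr__(self, "Y_mm", Y)
        if X.ndim != 1 or Y.ndim != 1 or X.size != Y.size:
            raise MidlineValidationError(
                "X and Y must be one-dimensional and of equal length"
            )
        if X.size < MIN_POINTS:
            raise MidlineValidationError(
                f"insufficient points: need at least {MIN_POINTS}, got {X.size}"
            )
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(Y)):
            raise MidlineValidationError("coordinates must be finite")
        bad = np.nonzero(np.diff(X) <= 0)[0]
        if bad.size:
            row = int(bad[0]) + 1  # first offending row, 0-based data row index
            raise MidlineValidationError(
                f"X must be strictly increasing; violated at row {row} "
                f"(X={X[row]} after X={X[row - 1]})"
            )

    def __len__(self) -> int:
        return int(self.X_mm.size)


@dataclass(frozen=True)
class BeamFrameCurve:
    """Midline re-expressed in the beam frame: station x (m) on [-h, +h]
    with the origin at the axial midpoint, lateral displacement y (m).

    ``origin_X_mm`` keeps the device-frame X of the origin so the
    transformation is invertible.
    """

    x_m: np.ndarray
    y_m: np.ndarray
    half_length_m: float
    origin_X_mm: float
    spacing_mm: float = 7.0

    def __post_init__(self):
        x = np.asarray(self.x_m, dtype=float)
        y = np.asarray(self.y_m, dtype=float)
        object.__setattr__(self, "x_m", x)
        object.__setattr__(self, "y_m", y)
        h = self.half_length_m
        if np.any(x < -h - 1e-12) or np.any(x > h + 1e-12):
            raise MidlineValidationError("stations must lie within [-h, +h]")
        if np.any(np.diff(x) <= 0):
            raise MidlineValidationError("stations must be strictly increasing")


@dataclass(frozen=True)
class PolynomialProfile:
    """Initial lateral displacement y0(x) as a polynomial in SI units.

    Coefficients are stored highest degree first, matching
    y0(x) = a3 x^3 + a2 x^2 + a1 x + a0 for the default cubic. Degrees above
    3 are permitted for sensitivity work but void the closed-form beam
    solution (the fourth derivative of y0 no longer vanishes).
    """

    coefficients: tuple[float, ...]
    degree: int = field(init=False)

    def __post_init__(self):
        coeffs = tuple(float(c) for c in self.coefficients)
        if not coeffs:
            raise FitError("empty coefficient vector")
        object.__setattr__(self, "coefficients", coeffs)
        object.__setattr__(self, "degree", len(coeffs) - 1)

    def __call__(self, x, order: int = 0):
        return profile_derivatives(self, x, order)


#: Cubic fitted to the bundled reference patient's midline (SI units).
REFERENCE_PROFILE = PolynomialProfile((-33.86561, -3.55545, 0.3189, 0.03345))


@dataclass(frozen=True)
class FitResult:
    """An OLS polynomial fit together with its residual report."""

    profile: PolynomialProfile
    rmse_m: float
    n_points: int

    def report(self, frame: BeamFrameCurve | None = None) -> dict:
        """JSON-ready fit report."""
        out = {
            "coefficients": list(self.profile.coefficients),
            "rmse_m": self.rmse_m,
            "n_points": self.n_points,
        }
        if frame is not None:
            out["frame"] = {
                "origin_X_mm": frame.origin_X_mm,
                "half_length_m": frame.half_length_m,
            }
        return out


def read_midline_csv(path) -> SpineCurve:
    """Read a midline coordinate CSV with header columns ``X_mm`` and
    ``Y_mm`` (any column order) into a validated :class:`SpineCurve`.

    Row order is preserved; validation errors name the offending row.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise MidlineParseError(f"cannot parse {path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    if "x_mm" not in cols or "y_mm" not in cols:
        raise MidlineParseError(
            f"{path}: expected columns 'X_mm' and 'Y_mm', found {list(df.columns)}"
        )
    sub = df[[cols["x_mm"], cols["y_mm"]]]
    try:
        arr = sub.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise MidlineParseError(f"{path}: non-numeric cell: {exc}") from exc
    X, Y = arr[:, 0], arr[:, 1]
    spacing = float(np.median(np.diff(X))) if X.size > 1 else 0.0
    return SpineCurve(X_mm=X, Y_mm=Y, spacing_mm=spacing)


def curve_length(curve: SpineCurve) -> float:
    """Axial extent of the scoliotic curve, max(X) - min(X), in mm."""
    return float(curve.X_mm[-1] - curve.X_mm[0])


def max_deviation(curve: SpineCurve) -> tuple[float, float]:
    """Largest |Y| and the X (mm) of the first point attaining it."""
    idx = int(np.argmax(np.abs(curve.Y_mm)))
    return float(np.abs(curve.Y_mm[idx])), float(curve.X_mm[idx])


def to_beam_frame(curve: SpineCurve) -> BeamFrameCurve:
    """Transform to the midpoint-origin beam frame in metres.

    The inferior end (first row) maps to x = -h and the superior end to
    x = +h; y keeps the sign of the lateral deviation.
    """
    L_mm = curve_length(curve)
    origin = float(curve.X_mm[0]) + L_mm / 2.0
    return BeamFrameCurve(
        x_m=(curve.X_mm - origin) / 1000.0,
        y_m=curve.Y_mm / 1000.0,
        half_length_m=L_mm / 2000.0,
        origin_X_mm=origin,
        spacing_mm=curve.spacing_mm,
    )


def from_beam_frame(frame: BeamFrameCurve) -> SpineCurve:
    """Invert :func:`to_beam_frame` back to the device frame (mm)."""
    return SpineCurve(
        X_mm=frame.x_m * 1000.0 + frame.origin_X_mm,
        Y_mm=frame.y_m * 1000.0,
        spacing_mm=frame.spacing_mm,
    )


def fit_initial_displacement(frame: BeamFrameCurve, degree: int = 3) -> FitResult:
    """Unweighted ordinary-least-squares polynomial fit of y0(x).

    Requires strictly more points than ``degree + 1`` and at least
    ``degree + 1`` distinct stations (otherwise the Vandermonde design is
    rank deficient).
    """
    x, y = frame.x_m, frame.y_m
    if x.size <= degree + 1:
        raise FitError(
            f"need more than {degree + 1} points for a degree-{degree} fit, got {x.size}"
        )
    if np.unique(x).size < degree + 1:
        raise FitError("rank-deficient fit: fewer distinct stations than coefficients")
    coeffs = np.polyfit(x, y, degree)
    resid = y - np.polyval(coeffs, x)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return FitResult(
        profile=PolynomialProfile(tuple(coeffs)),
        rmse_m=rmse,
        n_points=int(x.size),
    )


def profile_derivatives(profile: PolynomialProfile, x, order: int = 0):
    """Evaluate y0 or one of its analytic derivatives at station(s) x (m)."""
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    c = np.asarray(profile.coefficients, dtype=float)
    for _ in range(order):
        c = np.polyder(c)
    val = np.polyval(c, np.asarray(x, dtype=float))
    return float(val) if np.isscalar(x) or np.ndim(x) == 0 else val
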