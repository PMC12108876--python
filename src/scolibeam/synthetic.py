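"""Synthetic scoliotic-midline generator and the bundled reference series.

Emulates the structure of a digitized coronal midline: axial positions at
a fixed sampling interval (7 mm by default, matching the CT digitisation
of the bundled patient), zero lateral deviation at both end vertebrae, a
single interior apex of programmed magnitude, and optional i.i.d. Gaussian
digitisation noise on the lateral coordinate only (axial positions are
instrument-fixed). Two shape families are provided: ``cubic`` (a product
of root factors — exactly recoverable by the cubic fit) and ``half-sine``
(apex-warped sinusoid, a non-polynomial control shape).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import ScolibeamError
from .geometry import SpineCurve, read_midline_csv

__all__ = ["SyntheticSpec", "generate_midline", "reference_midline"]

logger = logging.getLogger(__name__)

_SHAPES = ("cubic", "half-sine")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic scoliotic midline.

    length_mm : axial extent of the curve (distance between end vertebrae).
    max_dev_mm : programmed apex deviation (before noise).
    apex_fraction : apex location along the curve, in (0, 1).
    spacing_mm : sampling interval (7 mm default).
    shape : "cubic" or "half-sine".
    noise_sd_mm : standard deviation of Gaussian noise added to Y.
    seed : seed for the noise generator; same seed, same output.
    """

    length_mm: float = 196.0
    max_dev_mm: float = 40.0
    apex_fraction: float = 0.5
    spacing_mm: float = 7.0
    shape: str = "cubic"
    noise_sd_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.length_mm <= 4 * self.spacing_mm:
            raise ScolibeamError("length must exceed four sampling intervals")
        if not 0.0 < self.apex_fraction < 1.0:
            raise ScolibeamError("apex_fraction must lie in (0, 1)")
        if self.max_dev_mm < 0:
            raise ScolibeamError("max_dev_mm must be non-negative")
        if self.shape not in _SHAPES:
            raise ScolibeamError(f"shape must be one of {_SHAPES}")
        if self.noise_sd_mm < 0:
            raise ScolibeamError("noise_sd_mm must be non-negative")


def _cubic_shape(t: np.ndarray, f: float) -> np.ndarray:
    """Cubic t(1-t)(a t + b), unit apex at t = f, zero at t = 0, 1."""
    # rows: d/dt [t(1-t)(a t + b)] = 0 at f ; value = 1 at f
    M = np.array(
        [
            [(1 - 2 * f) * f + f * (1 - f), (1 - 2 * f)],
            [f * f * (1 - f), f * (1 - f)],
        ]
    )
    a, b = np.linalg.solve(M, np.array([0.0, 1.0]))
    return t * (1 - t) * (a * t + b)


def _half_sine_shape(t: np.ndarray, f: float) -> np.ndarray:
    """sin(pi u(t)) with a piecewise-linear warp putting the apex at t = f."""
    u = np.where(t <= f, t / (2 * f), 0.5 + (t - f) / (2 * (1 - f)))
    return np.sin(np.pi * u)


def generate_midline(spec: SyntheticSpec) -> SpineCurve:
    """Generate a synthetic midline series per ``spec``.

    Axial positions run 0, spacing, 2·spacing, … ; if the spacing does not
    divide the length the final point is placed at the exact length
    (uneven last interval, logged as a warning). The deviation is zero at
    both ends before noise and attains ``max_dev_mm`` at the apex.
    """
    L, s = spec.length_mm, spec.spacing_mm
    n_steps = int(round(L / s)) if abs(round(L / s) * s - L) < 1e-9 else int(L // s)
    X = np.arange(n_steps + 1) * s
    if X[-1] < L - 1e-9:
        logger.warning(
            "spacing %.3g mm does not divide length %.3g mm; final point placed at "
            "the exact length (uneven last interval)",
            s,
            L,
        )
        X = np.append(X, L)
    t = X / L
    shape = _cubic_shape(t, spec.apex_fraction) if spec.shape == "cubic" else (
        _half_sine_shape(t, spec.apex_fraction)
    )
    peak = np.max(np.abs(shape))
    if peak > 1.0 + 1e-9:
        raise ScolibeamError(
            "cubic shape family has no single apex of programmed magnitude for "
            f"apex_fraction={spec.apex_fraction}; use shape='half-sine'"
        )
    Y = spec.max_dev_mm * shape
    if spec.noise_sd_mm > 0:
        rng = np.random.default_rng(spec.seed)
        Y = Y + rng.normal(0.0, spec.noise_sd_mm, size=Y.shape)
    return SpineCurve(X_mm=X, Y_mm=Y, spacing_mm=s)


def reference_midline() -> SpineCurve:
    """The bundled reference patient's midline: 29 points at 7 mm spacing
    digitized from the CT-derived coronal midline of an AIS volunteer,
    spanning 196 mm from the inferior to the superior end vertebra with a
    40.04 mm apex deviation."""
    with resources.as_file(
        resources.files("scolibeam.data").joinpath("reference_midline.csv")
    ) as p:
        return read_midline_csv(p)
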