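"""End-to-end pipeline: read -> frame transform -> fit -> solve -> plan
-> moment analysis, producing a single machine-readable report."""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path

import numpy as np

from .beam import BeamParameters, LoadCase, solve_bvp_numeric, solve_closed_form
from .config import RunConfig
from .errors import PipelineError, ScolibeamError
from .geometry import (
    curve_length,
    fit_initial_displacement,
    max_deviation,
    read_midline_csv,
    to_beam_frame,
)
from .moments import cobb_from_profile, crossover_angle, dominant_load, CobbGeometry
from .planner import (
    PlanningTarget,
    load_from_body_weight,
    required_axial_load,
    sessions_required,
    total_load_at_angle,
    tradeoff_curve,
)
from .synthetic import reference_midline

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "write_report"]


def _stage(name: str, hint: str, fn, *args, **kwargs):
    logger.info("stage %s: starting", name)
    try:
        out = fn(*args, **kwargs)
    except ScolibeamError as exc:
        raise PipelineError(name, str(exc), hint) from exc
    logger.info("stage %s: done", name)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full fit -> solve -> plan -> moments pipeline.

    Returns a JSON-ready report; every stage failure is surfaced as a
    :class:`PipelineError` naming the stage.
    """
    # --- ingest ---------------------------------------------------------
    if config.input_csv is None:
        curve = _stage("read", "check the bundled data installation", reference_midline)
    else:
        curve = _stage(
            "read", "check the CSV path and X_mm/Y_mm header",
            read_midline_csv, config.input_csv,
        )
    dev, dev_at = max_deviation(curve)
    L_mm = curve_length(curve)

    # --- fit ------------------------------------------------------------
    frame = _stage("frame", "midline must be strictly increasing in X", to_beam_frame, curve)
    fit = _stage("fit", "need more points than polynomial coefficients",
                 fit_initial_displacement, frame)
    profile = fit.profile

    params = BeamParameters(
        EI=config.patient.EI_Nm2,
        L=L_mm / 1000.0,
        Li=config.patient.Li_mm / 1000.0,
    )

    # --- recommended per-session loads ----------------------------------
    P_session = load_from_body_weight(
        config.patient.mass_kg, config.loads.axial_fraction, config.loads.g
    )
    Q_session = load_from_body_weight(
        config.patient.mass_kg, config.loads.lateral_fraction, config.loads.g
    )

    # --- forward solve at the recommended loads --------------------------
    load = LoadCase(P=P_session, Q=Q_session, alpha_deg=config.loads.alpha_deg)
    sol = _stage("solve", "axial load must be positive for the closed form",
                 solve_closed_form, profile, params, load)
    apex_x = (dev_at - frame.origin_X_mm) / 1000.0
    solve_block = {
        "P_session_N": P_session,
        "Q_session_N": Q_session,
        "alpha_deg": config.loads.alpha_deg,
        "y_at_apex_m": sol.total(apex_x),
        "y0_at_apex_m": profile(apex_x),
    }
    if config.numerics.numeric_cross_check:
        num = _stage("solve-numeric", "grid must be odd with >= 201 nodes",
                     solve_bvp_numeric, profile, params, load,
                     config.numerics.n_nodes)
        xs = np.linspace(-params.h, params.h, 41)
        solve_block["numeric_max_abs_diff_m"] = float(
            np.max(np.abs(np.asarray(sol.total(xs)) - np.asarray(num.total(xs))))
        )

    # --- required-load planning ------------------------------------------
    target = PlanningTarget(
        station=config.planning.station_m,
        target_displacement=config.planning.target_m,
    )
    P_required = _stage(
        "plan", "widen the bracket or move the planning station",
        required_axial_load, profile, params,
        0.0, target, config.planning.bracket_N, config.numerics.root_tol_N,
    )
    P_total = total_load_at_angle(P_required, config.loads.alpha_deg)
    plan_block = {
        "station_m": target.station,
        "target_m": target.target_displacement,
        "P_required_N": P_required,
        "alpha_deg": config.loads.alpha_deg,
        "P_total_N": P_total,
        "per_session_N": P_session,
        "sessions": sessions_required(P_total, P_session) if P_session > 0 else None,
    }
    if Q_session > 0:
        Qs = np.linspace(0.0, Q_session, config.tradeoff_Q_points)
        curve_po = _stage(
            "tradeoff", "each Q must admit a root in the bracket",
            tradeoff_curve, profile, params, target, tuple(Qs), config.planning.bracket_N,
        )
        plan_block["tradeoff"] = curve_po.as_dict()

    # --- moment analysis -------------------------------------------------
    theta = cobb_from_profile(profile, params.h)
    chord = params.L  # chord between end vertebrae, m
    comparison = dominant_load(P_session, Q_session, CobbGeometry(theta_deg=theta, d=chord))
    moments_block = {
        "cobb_estimate_deg": theta,
        "chord_m": chord,
        "M_P_Nm": comparison.M_P,
        "M_Q_Nm": comparison.M_Q,
        "dominant": comparison.dominant,
        "crossover_deg_equal_loads": crossover_angle(1.0, 1.0),
        "crossover_deg_session_loads": (
            crossover_angle(P_session, Q_session) if P_session > 0 else None
        ),
    }

    return {
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "input": {
            "source": config.input_csv or "bundled reference midline",
            "n_points": len(curve),
            "curve_length_mm": L_mm,
            "max_deviation_mm": dev,
            "max_deviation_at_X_mm": dev_at,
        },
        "fit": fit.report(frame),
        "solve": solve_block,
        "plan": plan_block,
        "moments": moments_block,
    }


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
    logger.info("report written to %s", path)
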