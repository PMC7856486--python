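"""Full daily-session evaluation: metrics, baseline comparison, classification.

One evaluated session bundles the operator-entered functional and
image-guidance booleans with the computed dosimetry checks.  Every
dosimetry check is a deviation from the commissioning baseline classified
against its tolerance family:

    |deviation| <  warn            -> pass
    warn <= |deviation| < fail     -> warning
    |deviation| >= fail            -> fail

Boundaries are inclusive upward, so a tolerance quoted as "±3%" passes
strictly inside 3%.  The session's overall status is the worst check
status, and any false functional/IGRT boolean forces overall fail.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field

from .grid_io import DoseGrid, central_profiles
from .field_metrics import (
    field_size,
    flatness,
    infer_range_shift,
    output_dose,
    range_dose,
    symmetry,
)
from .pattern import Baseline, PatternSpec, ToleranceSet
from .spot_metrics import analyze_spots

__all__ = [
    "CheckResult",
    "DQASession",
    "classify",
    "measure",
    "evaluate_session",
    "render_report",
    "VERSION",
]

VERSION = "0.1.0"

_STATUS_ORDER = {"pass": 0, "warning": 1, "fail": 2}


@dataclass
class CheckResult:
    """One classified metric deviation."""

    name: str  # e.g. "output", "spot_position:140MeV:x"
    family: str  # ToleranceSet family name
    measured: float | None
    baseline: float | None
    deviation: float | None  # measured - baseline, in the family's unit
    units: str
    status: str  # pass | warning | fail
    warn: float
    fail: float
    note: str = ""


@dataclass
class DQASession:
    """One day's evaluated daily-QA session."""

    date: _dt.date | None
    room: str
    functional_checks: dict[str, bool] = field(default_factory=dict)
    igrt_checks: dict[str, bool] = field(default_factory=dict)
    checks: list[CheckResult] = field(default_factory=list)
    overall: str = "pass"
    input_sha256: str = ""
    config_digest: str = ""


def classify(deviation: float, warn: float, fail: float) -> str:
    """Tier a deviation magnitude against warning/failure thresholds."""
    if not warn <= fail:
        raise ValueError("need warn <= fail")
    mag = abs(deviation)
    if mag >= fail:
        return "fail"
    if mag >= warn:
        return "warning"
    return "pass"


def _check(
    name: str,
    family: str,
    measured: float,
    baseline: float,
    deviation: float,
    units: str,
    tol: ToleranceSet,
) -> CheckResult:
    t = tol.for_family(family)
    return CheckResult(
        name, family, measured, baseline, deviation, units,
        classify(deviation, t.warn, t.fail), t.warn, t.fail,
    )


def _error_check(name: str, family: str, units: str, tol: ToleranceSet,
                 reason: str) -> CheckResult:
    t = tol.for_family(family)
    return CheckResult(name, family, None, None, None, units, "fail",
                       t.warn, t.fail, note=reason)


def measure(
    grid: DoseGrid,
    pattern: PatternSpec,
    resample_to_mm: float | None = None,
):
    """Compute all raw field metrics and spot fits for one measurement.

    Returns ``(FieldMetrics, list[SpotFit])`` with no baseline comparison —
    the input to :func:`protondqa.pattern.baseline_from_session` when
    commissioning a baseline from a nominal measurement.
    """
    from .field_metrics import FieldMetrics

    out = output_dose(grid, pattern.output_square)
    rd = range_dose(grid, pattern.range_square)
    sq = pattern.output_square
    prof_x, prof_y = central_profiles(grid, sq.center_x, sq.center_y)
    fx, _ = flatness(prof_x, sq.width_x, sq.center_x)
    fy, _ = flatness(prof_y, sq.width_y, sq.center_y)
    sx, _ = symmetry(prof_x, sq.width_x, sq.center_x)
    sy, _ = symmetry(prof_y, sq.width_y, sq.center_y)
    fsx = field_size(prof_x, sq.center_x)
    fsy = field_size(prof_y, sq.center_y)
    metrics = FieldMetrics(
        output_gy=out,
        flatness_x_pct=fx,
        flatness_y_pct=fy,
        symmetry_x_pct=sx,
        symmetry_y_pct=sy,
        field_size_x_mm=fsx,
        field_size_y_mm=fsy,
        range_dose_gy=rd,
    )
    fits = [f for f, _ in analyze_spots(grid, pattern, resample_to_mm=resample_to_mm)]
    return metrics, fits


def evaluate_session(
    grid: DoseGrid,
    pattern: PatternSpec,
    baseline: Baseline,
    tol: ToleranceSet | None = None,
    functional_checks: dict[str, bool] | None = None,
    igrt_checks: dict[str, bool] | None = None,
    ic2_dev_pct: float | None = None,
    resample_to_mm: float | None = None,
    input_sha256: str = "",
    config_digest: str = "",
) -> DQASession:
    """Evaluate one daily measurement against baseline and tolerances.

    Emits checks for output, range dose, inferred range shift, per-spot
    position (mm) and size (%) on both axes, flatness/symmetry/field size
    on both axes, and — when supplied — the operator-entered redundant
    monitor chamber (IC2) deviation.  Any metric computation error becomes
    a fail-status check carrying the reason; no exception escapes per
    metric.
    """
    tol = tol or ToleranceSet()
    checks: list[CheckResult] = []

    # output
    try:
        out = output_dose(grid, pattern.output_square)
        dev = (out - baseline.output_gy) / baseline.output_gy * 100.0
        checks.append(_check("output", "output_pct", out, baseline.output_gy,
                             dev, "%", tol))
    except Exception as exc:
        checks.append(_error_check("output", "output_pct", "%", tol, str(exc)))

    # range-dose surrogate and inferred range shift
    try:
        rd = range_dose(grid, pattern.range_square)
        rdev = (rd - baseline.range_dose_gy) / baseline.range_dose_gy * 100.0
        checks.append(_check("energy_dose", "energy_dose_pct", rd,
                             baseline.range_dose_gy, rdev, "%", tol))
        shift = infer_range_shift(rdev, baseline.range_sensitivity_pct_per_mm)
        checks.append(_check("range_shift", "range_mm", shift, 0.0, shift,
                             "mm", tol))
    except Exception as exc:
        checks.append(_error_check("energy_dose", "energy_dose_pct", "%", tol,
                                   str(exc)))
        checks.append(_error_check("range_shift", "range_mm", "mm", tol,
                                   str(exc)))

    # spots
    try:
        spot_results = analyze_spots(grid, pattern, resample_to_mm=resample_to_mm)
    except Exception as exc:
        spot_results = None
        for s in pattern.spots:
            tag = f"{s.energy:g}MeV"
            for ax in ("x", "y"):
                checks.append(_error_check(f"spot_position:{tag}:{ax}",
                                           "spot_position_mm", "mm", tol, str(exc)))
                checks.append(_error_check(f"spot_size:{tag}:{ax}",
                                           "spot_size_pct", "%", tol, str(exc)))
    if spot_results is not None:
        for (fit, dev), spec in zip(spot_results, pattern.spots):
            tag = f"{spec.energy:g}MeV"
            if dev is None:
                for ax in ("x", "y"):
                    checks.append(_error_check(f"spot_position:{tag}:{ax}",
                                               "spot_position_mm", "mm", tol,
                                               fit.reason or "fit did not converge"))
                    checks.append(_error_check(f"spot_size:{tag}:{ax}",
                                               "spot_size_pct", "%", tol,
                                               fit.reason or "fit did not converge"))
                continue
            checks.append(_check(f"spot_position:{tag}:x", "spot_position_mm",
                                 fit.mu_x, spec.baseline_mu_x, dev.d_mu_x, "mm", tol))
            checks.append(_check(f"spot_position:{tag}:y", "spot_position_mm",
                                 fit.mu_y, spec.baseline_mu_y, dev.d_mu_y, "mm", tol))
            checks.append(_check(f"spot_size:{tag}:x", "spot_size_pct",
                                 fit.sigma_x, spec.baseline_sigma_x,
                                 dev.d_sigma_x_pct, "%", tol))
            checks.append(_check(f"spot_size:{tag}:y", "spot_size_pct",
                                 fit.sigma_y, spec.baseline_sigma_y,
                                 dev.d_sigma_y_pct, "%", tol))

    # profiles of the output square: flatness, symmetry, field size
    sq = pattern.output_square
    try:
        prof_x, prof_y = central_profiles(grid, sq.center_x, sq.center_y)
        profs = {"x": prof_x, "y": prof_y}
    except Exception as exc:
        profs = None
        for ax in ("x", "y"):
            checks.append(_error_check(f"flatness:{ax}", "flatness_pct", "%",
                                       tol, str(exc)))
            checks.append(_error_check(f"symmetry:{ax}", "symmetry_pct", "%",
                                       tol, str(exc)))
            checks.append(_error_check(f"field_size:{ax}", "field_size_mm",
                                       "mm", tol, str(exc)))
    if profs is not None:
        base_flat = {"x": baseline.flatness_x_pct, "y": baseline.flatness_y_pct}
        base_symm = {"x": baseline.symmetry_x_pct, "y": baseline.symmetry_y_pct}
        base_fs = {"x": baseline.field_size_x_mm, "y": baseline.field_size_y_mm}
        widths = {"x": sq.width_x, "y": sq.width_y}
        centers = {"x": sq.center_x, "y": sq.center_y}
        for ax in ("x", "y"):
            p = profs[ax]
            try:
                f, _ = flatness(p, widths[ax], centers[ax])
                checks.append(_check(f"flatness:{ax}", "flatness_pct", f,
                                     base_flat[ax], f - base_flat[ax], "%", tol))
            except Exception as exc:
                checks.append(_error_check(f"flatness:{ax}", "flatness_pct",
                                           "%", tol, str(exc)))
            try:
                s, _ = symmetry(p, widths[ax], centers[ax])
                checks.append(_check(f"symmetry:{ax}", "symmetry_pct", s,
                                     base_symm[ax], s - base_symm[ax], "%", tol))
            except Exception as exc:
                checks.append(_error_check(f"symmetry:{ax}", "symmetry_pct",
                                           "%", tol, str(exc)))
            try:
                fs = field_size(p, centers[ax])
                checks.append(_check(f"field_size:{ax}", "field_size_mm", fs,
                                     base_fs[ax], fs - base_fs[ax], "mm", tol))
            except Exception as exc:
                checks.append(_error_check(f"field_size:{ax}", "field_size_mm",
                                           "mm", tol, str(exc)))

    # operator-entered redundant monitor chamber constancy
    if ic2_dev_pct is not None:
        checks.append(_check("ic2", "ic2_pct", ic2_dev_pct, 0.0, ic2_dev_pct,
                             "%", tol))

    functional_checks = dict(functional_checks or {})
    igrt_checks = dict(igrt_checks or {})
    overall = max((c.status for c in checks), key=_STATUS_ORDER.get,
                  default="pass")
    if not all(functional_checks.values()) or not all(igrt_checks.values()):
        overall = "fail"
    return DQASession(
        date=grid.date,
        room=grid.room,
        functional_checks=functional_checks,
        igrt_checks=igrt_checks,
        checks=checks,
        overall=overall,
        input_sha256=input_sha256,
        config_digest=config_digest,
    )


def render_report(session: DQASession) -> str:
    """Serialize a session as a deterministic JSON report."""
    doc = {
        "session": {
            "date": session.date.isoformat() if session.date else None,
            "room": session.room,
            "overall": session.overall,
        },
        "functional": session.functional_checks,
        "igrt": session.igrt_checks,
        "checks": [
            {
                "name": c.name,
                "family": c.family,
                "measured": c.measured,
                "baseline": c.baseline,
                "deviation": c.deviation,
                "units": c.units,
                "status": c.status,
                "thresholds": {"warn": c.warn, "fail": c.fail},
                **({"note": c.note} if c.note else {}),
            }
            for c in session.checks
        ],
        "provenance": {
            "input_sha256": session.input_sha256,
            "version": VERSION,
            "config_digest": session.config_digest,
        },
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
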