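"""Output, flatness, symmetry, field size and the range-dose surrogate.

All field metrics are constancy checks on the two square fields of the
daily pattern:

* output — mean dose in the central 3x3 cm^2 of the 10x10 cm output square;
* lateral flatness — (d_max - d_min)/(d_max + d_min) x 100 over the central
  80% of the field on a central-axis profile;
* lateral symmetry — worst mirrored-pair ratio (D1 - D2)/(D1 + D2) x 100
  over the same region;
* field size — distance between the two 50%-isodose crossings of a profile;
* range surrogate — mean dose in the center of the range-check square; a
  range shift of 1 mm moves this dose by ~12% (the sensitivity `s`), so the
  measured dose deviation divides into an inferred range shift in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid_io import DoseGrid, Profile, extract_roi
from .pattern import SquareSpec

__all__ = [
    "ProfileStats",
    "FieldMetrics",
    "output_dose",
    "flatness",
    "symmetry",
    "field_size",
    "range_dose",
    "infer_range_shift",
    "OUTPUT_WINDOW_MM",
    "RANGE_WINDOW_MM",
    "FLAT_REGION_FRACTION",
]

OUTPUT_WINDOW_MM = 30.0  # side of the central output-averaging square
RANGE_WINDOW_MM = (10.0, 20.0)  # (x, y) central window of the range square
FLAT_REGION_FRACTION = 0.8  # flatness/symmetry evaluated on central 80%


@dataclass
class ProfileStats:
    """Audit record of the doses entering a flatness/symmetry value."""

    d_max: float
    d_min: float
    d1: float  # mirrored pair realizing the worst asymmetry
    d2: float
    region_lo: float  # evaluated interval, mm
    region_hi: float


@dataclass
class FieldMetrics:
    """All field-level metrics of one measured pattern."""

    output_gy: float
    flatness_x_pct: float
    flatness_y_pct: float
    symmetry_x_pct: float
    symmetry_y_pct: float
    field_size_x_mm: float
    field_size_y_mm: float
    range_dose_gy: float
    range_dose_dev_pct: float | None = None
    inferred_range_shift_mm: float | None = None


def output_dose(grid: DoseGrid, square: SquareSpec) -> float:
    """Mean dose over the central 3x3 cm^2 window of the output square."""
    half = OUTPUT_WINDOW_MM / 2
    roi = extract_roi(
        grid, square.center_x, square.center_y, half, half, require_complete=True
    )
    return float(roi.values.mean())


def _region(field_size_mm: float, center: float) -> tuple[float, float]:
    half = FLAT_REGION_FRACTION * field_size_mm / 2
    return center - half, center + half


def flatness(
    profile: Profile, field_size_mm: float, axis_center_mm: float = 0.0
) -> tuple[float, ProfileStats]:
    """Lateral flatness (%) over the central 80% of the field."""
    lo, hi = _region(field_size_mm, axis_center_mm)
    if profile.positions[0] > lo or profile.positions[-1] < hi:
        raise ValueError("profile does not cover the evaluation region")
    mask = (profile.positions >= lo) & (profile.positions <= hi)
    d = profile.doses[mask]
    d_max, d_min = float(d.max()), float(d.min())
    if d_max + d_min == 0:
        raise ValueError("zero dose over the evaluation region")
    val = (d_max - d_min) / (d_max + d_min) * 100.0
    return val, ProfileStats(d_max, d_min, d_max, d_min, lo, hi)


def symmetry(
    profile: Profile, field_size_mm: float, axis_center_mm: float = 0.0
) -> tuple[float, ProfileStats]:
    """Lateral symmetry (%): worst mirrored-pair deviation about the axis.

    The profile is linearly interpolated onto mirrored position pairs
    (c - u, c + u) at 1 mm steps of u within the central 80% region; the
    returned value is max |D1 - D2| / (D1 + D2) x 100 with the maximizing
    pair recorded.
    """
    lo, hi = _region(field_size_mm, axis_center_mm)
    if profile.positions[0] > lo or profile.positions[-1] < hi:
        raise ValueError("profile does not cover the evaluation region")
    half = FLAT_REGION_FRACTION * field_size_mm / 2
    u = np.arange(0.0, half + 1e-9, 1.0)
    d1 = np.interp(axis_center_mm + u, profile.positions, profile.doses)
    d2 = np.interp(axis_center_mm - u, profile.positions, profile.doses)
    denom = d1 + d2
    if np.any(denom == 0):
        raise ValueError("zero dose over the evaluation region")
    ratios = np.abs(d1 - d2) / denom * 100.0
    k = int(np.argmax(ratios))
    stats = ProfileStats(
        float(np.max(np.concatenate([d1, d2]))),
        float(np.min(np.concatenate([d1, d2]))),
        float(d1[k]),
        float(d2[k]),
        lo,
        hi,
    )
    return float(ratios[k]), stats


def field_size(profile: Profile, center_mm: float = 0.0) -> float:
    """Distance (mm) between the two 50%-isodose crossings of a profile.

    The 50% reference level is half the dose at the sample nearest
    ``center_mm`` (the field's central axis) — not half the profile
    maximum, so a noise spike cannot shrink the field.  Each crossing is
    located by linear interpolation between the straddling samples; with
    multiple plateau segments the outermost crossings are used and a
    warning is emitted.
    """
    pos, dose = profile.positions, profile.doses
    k = int(np.argmin(np.abs(pos - center_mm)))
    level = dose[k] / 2.0
    if dose[k] <= 0:
        raise ValueError("zero dose on the central axis")
    above = dose >= level
    if not above.any():
        raise ValueError("profile never reaches the 50% level")
    idx = np.where(above)[0]
    first, last = idx[0], idx[-1]
    if first == 0:
        raise ValueError("50% level never crossed on the low side")
    if last == len(dose) - 1:
        raise ValueError("50% level never crossed on the high side")

    def cross(i0, i1):
        # linear interpolation of the crossing between samples i0 and i1
        d0, d1 = dose[i0], dose[i1]
        return pos[i0] + (level - d0) / (d1 - d0) * (pos[i1] - pos[i0])

    left = cross(first - 1, first)
    right = cross(last, last + 1)
    # crossings between first and last indicate multiple plateau segments
    interior = above[first : last + 1]
    if not interior.all():
        warnings.warn("multiple plateau segments; using outermost crossings",
                      stacklevel=2)
    return float(right - left)


def range_dose(grid: DoseGrid, square: SquareSpec) -> float:
    """Mean dose over the central window of the range-check square."""
    hx, hy = RANGE_WINDOW_MM[0] / 2, RANGE_WINDOW_MM[1] / 2
    roi = extract_roi(
        grid, square.center_x, square.center_y, hx, hy, require_complete=True
    )
    return float(roi.values.mean())


def infer_range_shift(dose_dev_pct: float, sensitivity_pct_per_mm: float) -> float:
    """Convert a range-dose deviation (%) into a range shift (mm).

    Linearized model: positive shift = range increase = dose increase at
    the measurement depth.  Odd and linear in the dose deviation.
    """
    if not sensitivity_pct_per_mm > 0:
        raise ValueError("sensitivity must be positive")
    return dose_dev_pct / sensitivity_pct_per_mm
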