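"""Synthetic measurement generator with injectable ground-truth drifts.

Emulates the daily measurement: the ideal dose of the composite test
pattern (seven Gaussian spots plus two square fields with Gaussian-blurred
penumbra edges) sampled at the detector's native pixel centers, with
multiplicative per-pixel Gaussian noise.  Machine misbehavior is injected
through :class:`TruthParams`: a global output scale, a range shift
converted to range-square dose through the linear ~12 %/mm sensitivity,
per-energy spot offsets and sigma scales, and a global setup shift of the
whole pattern.

The squares are modeled as separable products of smoothed-step edge
profiles (a slab convolved with a Gaussian of width ``edge_sigma_mm``),
which puts exactly 50% of the plateau dose at the nominal edge — the
anchor for field-size recovery.  They are not built from individual
scanned spots; intra-field spot structure is never needed by the analysis.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr

from .grid_io import DoseGrid, resample
from .pattern import DEFAULT_RANGE_SENSITIVITY, PatternSpec, SquareSpec

__all__ = [
    "TruthParams",
    "DetectorModel",
    "ideal_dose",
    "simulate_measurement",
    "simulate_series",
]


@dataclass
class TruthParams:
    """Ground-truth machine state for one simulated measurement."""

    output_scale: float = 1.0  # multiplies every plateau/spot dose
    range_shift_mm: float = 0.0  # positive = range increase = more dose
    spot_offset: dict[float, tuple[float, float]] = field(default_factory=dict)
    spot_sigma_scale: dict[float, float] = field(default_factory=dict)
    setup_shift: tuple[float, float] = (0.0, 0.0)  # global (dx, dy), mm
    noise_pct: float = 0.0  # sd of multiplicative Gaussian noise, % of dose
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.output_scale > 0:
            raise ValueError("output_scale must be positive")
        if any(s <= 0 for s in self.spot_sigma_scale.values()):
            raise ValueError("sigma scales must be positive")
        if self.noise_pct < 0:
            raise ValueError("noise_pct must be non-negative")


@dataclass
class DetectorModel:
    """Geometry of the emulated 2D array and its export."""

    pitch_mm: float = 7.6  # native ion-chamber pitch
    rows: int = 32
    cols: int = 32
    export_spacing_mm: float = 1.0  # interpolated vendor-export pitch
    edge_sigma_mm: float = 4.0  # square penumbra width parameter

    def __post_init__(self) -> None:
        if not self.pitch_mm > 0:
            raise ValueError("pitch must be positive")
        if self.export_spacing_mm > self.pitch_mm:
            raise ValueError("export spacing must not exceed native pitch")


def _edge_profile(u, center, width, edge_sigma):
    """Separable square-edge factor: 1 inside, 0 outside, 0.5 at the edge."""
    left = center - width / 2
    right = center + width / 2
    return ndtr((u - left) / edge_sigma) - ndtr((u - right) / edge_sigma)


def _square_dose(sq: SquareSpec, truth: TruthParams, x, y, edge_sigma, sensitivity):
    dx, dy = truth.setup_shift
    d = (
        sq.plateau_dose
        * truth.output_scale
        * _edge_profile(x, sq.center_x + dx, sq.width_x, edge_sigma)
        * _edge_profile(y, sq.center_y + dy, sq.width_y, edge_sigma)
    )
    if sq.kind == "range":
        d = d * (1.0 + sensitivity * truth.range_shift_mm / 100.0)
    return d


def ideal_dose(
    pattern: PatternSpec,
    truth: TruthParams,
    x,
    y,
    edge_sigma_mm: float = 4.0,
    range_sensitivity_pct_per_mm: float = DEFAULT_RANGE_SENSITIVITY,
):
    """Noise-free dose (Gy) of the drifted pattern at point(s) (x, y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dose = np.zeros(np.broadcast(x, y).shape)
    sdx, sdy = truth.setup_shift
    for s in pattern.spots:
        ox, oy = truth.spot_offset.get(s.energy, (0.0, 0.0))
        scale = truth.spot_sigma_scale.get(s.energy, 1.0)
        cx = s.nominal_x + ox + sdx
        cy = s.nominal_y + oy + sdy
        sx = s.baseline_sigma_x * scale
        sy = s.baseline_sigma_y * scale
        A = s.amplitude_gy * truth.output_scale
        dose = dose + A * np.exp(
            -0.5 * (((x - cx) / sx) ** 2 + ((y - cy) / sy) ** 2)
        )
    for sq in (pattern.output_square, pattern.range_square):
        dose = dose + _square_dose(
            sq, truth, x, y, edge_sigma_mm, range_sensitivity_pct_per_mm
        )
    return dose if dose.shape else float(dose)


def simulate_measurement(
    pattern: PatternSpec,
    truth: TruthParams,
    det: DetectorModel | None = None,
    export: bool = False,
    room: str = "TR1",
    date: _dt.date | None = None,
    range_sensitivity_pct_per_mm: float = DEFAULT_RANGE_SENSITIVITY,
) -> DoseGrid:
    """One simulated measurement at the detector's native pixel centers.

    Samples the ideal dose at the native lattice, applies multiplicative
    Gaussian noise ``d * (1 + eps)``, ``eps ~ N(0, noise_pct/100)`` from a
    generator seeded by ``truth.seed`` (reproducible), clamps negatives to
    zero, and optionally resamples to the interpolated export pitch.
    """
    det = det or DetectorModel()
    j = np.arange(det.cols)
    i = np.arange(det.rows)
    xs = (j - (det.cols - 1) / 2) * det.pitch_mm
    ys = ((det.rows - 1) / 2 - i) * det.pitch_mm
    X, Y = np.meshgrid(xs, ys)
    vals = ideal_dose(
        pattern, truth, X, Y,
        edge_sigma_mm=det.edge_sigma_mm,
        range_sensitivity_pct_per_mm=range_sensitivity_pct_per_mm,
    )
    if truth.noise_pct > 0:
        rng = np.random.default_rng(truth.seed)
        vals = vals * (1.0 + rng.normal(0.0, truth.noise_pct / 100.0, vals.shape))
    grid = DoseGrid(
        values=np.clip(vals, 0.0, None),
        spacing_mm=det.pitch_mm,
        room=room,
        date=date,
    )
    if export:
        grid = resample(grid, det.export_spacing_mm)
    return grid


def simulate_series(
    pattern: PatternSpec,
    base: TruthParams,
    n_days: int,
    drift: dict[str, float] | None = None,
    det: DetectorModel | None = None,
    seed: int = 0,
    start_date: _dt.date = _dt.date(2024, 1, 1),
    room: str = "TR1",
) -> list[tuple[_dt.date, DoseGrid]]:
    """Daily series: day k uses truth = base + k * drift, fresh noise substream.

    ``drift`` maps scalar TruthParams field names (``output_scale``,
    ``range_shift_mm``, ``noise_pct``, ``setup_shift_x``, ``setup_shift_y``)
    to per-day increments.  Each day's noise seed derives from ``(seed, k)``
    via numpy's SeedSequence spawning, so days are independent and the
    whole series reproducible.
    """
    det = det or DetectorModel()
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    drift = drift or {}
    allowed = {"output_scale", "range_shift_mm", "noise_pct",
               "setup_shift_x", "setup_shift_y"}
    unknown = set(drift) - allowed
    if unknown:
        raise ValueError(f"unknown drift fields: {sorted(unknown)}")
    out = []
    ss = np.random.SeedSequence(seed)
    day_seeds = ss.generate_state(n_days) >> np.uint32(1)  # keep below 2**31
    for k in range(n_days):
        sdx = base.setup_shift[0] + k * drift.get("setup_shift_x", 0.0)
        sdy = base.setup_shift[1] + k * drift.get("setup_shift_y", 0.0)
        truth = replace(
            base,
            output_scale=base.output_scale + k * drift.get("output_scale", 0.0),
            range_shift_mm=base.range_shift_mm + k * drift.get("range_shift_mm", 0.0),
            noise_pct=base.noise_pct + k * drift.get("noise_pct", 0.0),
            setup_shift=(sdx, sdy),
            seed=int(day_seeds[k]),
        )
        date = start_date + _dt.timedelta(days=k)
        out.append((date, simulate_measurement(pattern, truth, det, room=room, date=date)))
    return out
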