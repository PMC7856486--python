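"""Daily test-pattern geometry, commissioning baselines and tolerances.

The daily dosimetry plan delivers, in one composite irradiation: seven
single-energy pencil-beam spots (80-240 MeV) for spot position/size
constancy, a 3x4 cm^2 range-check square whose dose at the measurement
depth is a surrogate for proton range (~12% dose change per mm of range),
and a 10x10 cm^2 output square whose central region gives the machine
output.  Every daily metric is a deviation from a commissioning baseline;
the tolerance table classifies each deviation as pass / warning / fail.

The exact spot coordinates of the clinical plan are site-specific; the
default layout here keeps the published geometry (seven energies, the two
squares at their 50%-isodose dimensions, spots placed clear of both
squares) and everything is overridable through a YAML config.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace, asdict
from typing import Any

import yaml

__all__ = [
    "SpotSpec",
    "SquareSpec",
    "PatternSpec",
    "Baseline",
    "Tolerance",
    "ToleranceSet",
    "default_pattern",
    "default_tolerances",
    "default_baseline",
    "baseline_from_session",
    "default_config",
    "load_config",
    "save_config",
]

DEFAULT_RANGE_SENSITIVITY = 12.0  # %/mm dose change per mm of range shift


@dataclass
class SpotSpec:
    """One pristine-energy spot: planned position plus commissioned references."""

    energy: float  # MeV
    nominal_x: float  # planned center, mm
    nominal_y: float
    baseline_mu_x: float  # commissioned center, mm
    baseline_mu_y: float
    baseline_sigma_x: float  # commissioned Gaussian sigma, mm
    baseline_sigma_y: float
    amplitude_gy: float = 0.5  # simulator peak dose; never itself a QA metric

    def __post_init__(self) -> None:
        if not self.energy > 0:
            raise ValueError("energy must be positive")
        if not (self.baseline_sigma_x > 0 and self.baseline_sigma_y > 0):
            raise ValueError("baseline sigmas must be positive")


@dataclass
class SquareSpec:
    """A square field of the test pattern, sized at its 50% isodose line."""

    kind: str  # "output" | "range"
    center_x: float
    center_y: float
    width_x: float  # nominal 50%-isodose dimension, mm
    width_y: float
    plateau_dose: float  # Gy

    def __post_init__(self) -> None:
        if self.kind not in ("output", "range"):
            raise ValueError("kind must be 'output' or 'range'")
        if not (self.width_x > 0 and self.width_y > 0):
            raise ValueError("widths must be positive")
        if not self.plateau_dose > 0:
            raise ValueError("plateau_dose must be positive")


@dataclass
class PatternSpec:
    spots: list[SpotSpec]
    output_square: SquareSpec
    range_square: SquareSpec
    # spots must stay clear of both squares so each ROI sees a single spot
    min_spot_square_clearance: float = 30.0

    def __post_init__(self) -> None:
        seen = set()
        for s in self.spots:
            key = (s.nominal_x, s.nominal_y)
            if key in seen:
                raise ValueError("spot nominal positions must be pairwise distinct")
            seen.add(key)
        for sq in (self.output_square, self.range_square):
            for s in self.spots:
                dx = abs(s.nominal_x - sq.center_x) - sq.width_x / 2
                dy = abs(s.nominal_y - sq.center_y) - sq.width_y / 2
                if max(dx, dy) < self.min_spot_square_clearance:
                    raise ValueError(
                        f"spot {s.energy} MeV at ({s.nominal_x}, {s.nominal_y}) is "
                        f"within {self.min_spot_square_clearance} mm of the "
                        f"{sq.kind} square edge"
                    )

    def spot(self, energy: float) -> SpotSpec:
        for s in self.spots:
            if s.energy == energy:
                return s
        raise KeyError(f"no spot with energy {energy} MeV")


@dataclass
class Baseline:
    """Commissioning reference values every daily metric is compared against.

    Per-spot baselines (mu, sigma) live on each :class:`SpotSpec`.
    Flatness/symmetry references are per axis because the daily evaluation
    measures both profiles.
    """

    output_gy: float
    range_dose_gy: float
    range_sensitivity_pct_per_mm: float = DEFAULT_RANGE_SENSITIVITY
    flatness_x_pct: float = 0.0
    flatness_y_pct: float = 0.0
    symmetry_x_pct: float = 0.0
    symmetry_y_pct: float = 0.0
    field_size_x_mm: float = 100.0
    field_size_y_mm: float = 100.0
    date: _dt.date | None = None

    def __post_init__(self) -> None:
        if not self.output_gy > 0:
            raise ValueError("output_gy must be positive")
        if not self.range_dose_gy > 0:
            raise ValueError("range_dose_gy must be positive")
        if not self.range_sensitivity_pct_per_mm > 0:
            raise ValueError("range_sensitivity_pct_per_mm must be positive")


@dataclass(frozen=True)
class Tolerance:
    """Warning and failure thresholds for one metric family (same units as
    the metric's deviation)."""

    warn: float
    fail: float

    def __post_init__(self) -> None:
        if not (0 < self.warn <= self.fail):
            raise ValueError("need 0 < warn <= fail")


@dataclass
class ToleranceSet:
    """Thresholds per metric family.

    Defaults follow the clinical tolerance table: output and the range-dose
    surrogate use 3% warning / 5% failure zones; the inferred range shift
    is held to 1 mm; spot position passes below 1.0 mm and fails at 1.5 mm;
    spot size, flatness, symmetry, field size and the redundant monitor
    chamber (IC2) each have a single action level.
    """

    output_pct: Tolerance = field(default_factory=lambda: Tolerance(3.0, 5.0))
    energy_dose_pct: Tolerance = field(default_factory=lambda: Tolerance(3.0, 5.0))
    range_mm: Tolerance = field(default_factory=lambda: Tolerance(1.0, 1.0))
    spot_position_mm: Tolerance = field(default_factory=lambda: Tolerance(1.0, 1.5))
    spot_size_pct: Tolerance = field(default_factory=lambda: Tolerance(10.0, 10.0))
    flatness_pct: Tolerance = field(default_factory=lambda: Tolerance(2.0, 2.0))
    symmetry_pct: Tolerance = field(default_factory=lambda: Tolerance(2.0, 2.0))
    field_size_mm: Tolerance = field(default_factory=lambda: Tolerance(2.0, 2.0))
    ic2_pct: Tolerance = field(default_factory=lambda: Tolerance(2.0, 2.0))

    def for_family(self, family: str) -> Tolerance:
        try:
            return getattr(self, family)
        except AttributeError:
            raise KeyError(f"unknown tolerance family '{family}'") from None


_DEFAULT_ENERGIES = (80.0, 110.0, 140.0, 160.0, 180.0, 210.0, 240.0)
# simulator defaults, monotonically decreasing with energy (higher energy
# scatters less and arrives sharper); config values, not physics claims
_DEFAULT_SIGMAS = (6.5, 5.5, 4.8, 4.4, 4.0, 3.5, 3.0)
_DEFAULT_SPOT_X = (-90.0, -60.0, -30.0, 0.0, 30.0, 60.0, 90.0)
_DEFAULT_SPOT_Y = -80.0


def default_pattern() -> PatternSpec:
    """The default daily test pattern.

    Seven spots in a row below the output square, the 10x10 cm output
    square on the beam axis, and the 3x4 cm range-check square in the
    upper-left quadrant, all inside a 32x32-pixel, 7.6 mm-pitch detector.
    """
    spots = [
        SpotSpec(
            energy=e,
            nominal_x=x,
            nominal_y=_DEFAULT_SPOT_Y,
            baseline_mu_x=x,
            baseline_mu_y=_DEFAULT_SPOT_Y,
            baseline_sigma_x=s,
            baseline_sigma_y=s,
        )
        for e, x, s in zip(_DEFAULT_ENERGIES, _DEFAULT_SPOT_X, _DEFAULT_SIGMAS)
    ]
    output_square = SquareSpec("output", 0.0, 0.0, 100.0, 100.0, 1.0)
    range_square = SquareSpec("range", -90.0, 60.0, 30.0, 40.0, 1.0)
    return PatternSpec(spots, output_square, range_square)


def default_tolerances() -> ToleranceSet:
    return ToleranceSet()


def default_baseline() -> Baseline:
    """Idealized baseline matching the default pattern's nominal geometry."""
    return Baseline(
        output_gy=1.0,
        range_dose_gy=1.0,
        field_size_x_mm=100.0,
        field_size_y_mm=100.0,
    )


def baseline_from_session(
    field_metrics: "FieldMetrics",
    spot_fits: list["SpotFit"],
    pattern: PatternSpec,
    sensitivity_pct_per_mm: float = DEFAULT_RANGE_SENSITIVITY,
    date: _dt.date | None = None,
) -> tuple[Baseline, PatternSpec]:
    """Commission a baseline from a measurement declared nominal.

    Copies each measured field metric into the baseline and each spot fit's
    mu/sigma into a new :class:`PatternSpec` (per-spot baselines live
    there).  The range sensitivity is configuration, not measured, so it is
    passed through unchanged.  Raises if any spot fit failed to converge or
    is missing.
    """
    fits = {f.energy: f for f in spot_fits}
    new_spots = []
    for s in pattern.spots:
        f = fits.get(s.energy)
        if f is None:
            raise ValueError(f"missing spot fit for {s.energy} MeV")
        if not f.converged:
            raise ValueError(f"spot fit for {s.energy} MeV did not converge")
        new_spots.append(
            replace(
                s,
                baseline_mu_x=f.mu_x,
                baseline_mu_y=f.mu_y,
                baseline_sigma_x=f.sigma_x,
                baseline_sigma_y=f.sigma_y,
            )
        )
    for name in (
        "output_gy",
        "range_dose_gy",
        "flatness_x_pct",
        "flatness_y_pct",
        "symmetry_x_pct",
        "symmetry_y_pct",
        "field_size_x_mm",
        "field_size_y_mm",
    ):
        if getattr(field_metrics, name, None) is None:
            raise ValueError(f"measurement is missing metric '{name}'")
    baseline = Baseline(
        output_gy=field_metrics.output_gy,
        range_dose_gy=field_metrics.range_dose_gy,
        range_sensitivity_pct_per_mm=sensitivity_pct_per_mm,
        flatness_x_pct=field_metrics.flatness_x_pct,
        flatness_y_pct=field_metrics.flatness_y_pct,
        symmetry_x_pct=field_metrics.symmetry_x_pct,
        symmetry_y_pct=field_metrics.symmetry_y_pct,
        field_size_x_mm=field_metrics.field_size_x_mm,
        field_size_y_mm=field_metrics.field_size_y_mm,
        date=date,
    )
    new_pattern = replace(pattern, spots=new_spots)
    return baseline, new_pattern


# ---------------------------------------------------------------------------
# YAML config


def default_config() -> dict[str, Any]:
    """The packaged defaults as a plain config mapping."""
    return {
        "pattern": _pattern_to_dict(default_pattern()),
        "baseline": _baseline_to_dict(default_baseline()),
        "tolerances": _tolerances_to_dict(default_tolerances()),
    }


def load_config(path=None) -> tuple[PatternSpec, Baseline, ToleranceSet]:
    """Load pattern/baseline/tolerances from YAML; defaults where absent."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section in ("pattern", "baseline", "tolerances"):
            if section in user:
                cfg[section] = _merge(cfg[section], user[section])
    return (
        _pattern_from_dict(cfg["pattern"]),
        _baseline_from_dict(cfg["baseline"]),
        _tolerances_from_dict(cfg["tolerances"]),
    )


def save_config(
    path,
    pattern: PatternSpec | None = None,
    baseline: Baseline | None = None,
    tolerances: ToleranceSet | None = None,
) -> None:
    cfg = {
        "pattern": _pattern_to_dict(pattern or default_pattern()),
        "baseline": _baseline_to_dict(baseline or default_baseline()),
        "tolerances": _tolerances_to_dict(tolerances or default_tolerances()),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _merge(base: dict, user: dict) -> dict:
    out = dict(base)
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _pattern_to_dict(p: PatternSpec) -> dict:
    return {
        "spots": [asdict(s) for s in p.spots],
        "output_square": asdict(p.output_square),
        "range_square": asdict(p.range_square),
    }


def _pattern_from_dict(d: dict) -> PatternSpec:
    return PatternSpec(
        spots=[SpotSpec(**s) for s in d["spots"]],
        output_square=SquareSpec(**d["output_square"]),
        range_square=SquareSpec(**d["range_square"]),
    )


def _baseline_to_dict(b: Baseline) -> dict:
    d = asdict(b)
    d["date"] = b.date.isoformat() if b.date else None
    return d


def _baseline_from_dict(d: dict) -> Baseline:
    d = dict(d)
    if d.get("date"):
        d["date"] = _dt.date.fromisoformat(str(d["date"]))
    else:
        d["date"] = None
    return Baseline(**d)


def _tolerances_to_dict(t: ToleranceSet) -> dict:
    return {
        fam: {"warn": tol.warn, "fail": tol.fail}
        for fam, tol in vars(t).items()
    }


def _tolerances_from_dict(d: dict) -> ToleranceSet:
    return ToleranceSet(
        **{fam: Tolerance(v["warn"], v["fail"]) for fam, v in d.items()}
    )
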