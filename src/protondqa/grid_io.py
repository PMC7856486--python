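"""2D dose-grid data model, ASCII file I/O, resampling and profile extraction.

The measurement device emulated throughout this package is an ion-chamber
2D array with a native pixel pitch of 7.6 mm; its vendor export may also be
an interpolated 1 mm grid.  Grids live in the beam's-eye-view plane at
isocenter: +x runs left to right, +y runs in to out (away from the gantry),
and the geometric center of the grid sits on the beam axis at (0, 0).
Pixel values are point samples of absorbed dose (Gy) at pixel centers.

Files use the DQA-GRID v1 dialect: a ``# DQA-GRID v1`` magic line,
``key: value`` headers (``rows``, ``cols``, ``spacing_mm``, ``units: Gy``,
``origin: center`` required; ``room``, ``date``, ``interpolated`` optional),
then ``rows`` lines of ``cols`` whitespace-separated doses with row 0 at the
largest y.  Doses are written at full float precision.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "DoseGrid",
    "Profile",
    "GridParseError",
    "read_grid",
    "write_grid",
    "resample",
    "extract_roi",
    "central_profiles",
]

_MAGIC = "# DQA-GRID v1"


class GridParseError(ValueError):
    """Raised when a DQA-GRID file is malformed; message names the line."""


@dataclass
class DoseGrid:
    """A 2D absorbed-dose matrix with physical beam's-eye-view coordinates.

    ``values[i, j]`` is the dose at ``(x_j, y_i)`` where column j maps to
    ``x = center_x + (j - (cols-1)/2) * spacing_mm`` and row i to
    ``y = center_y + ((rows-1)/2 - i) * spacing_mm`` (row 0 = largest y).
    ``center_x/center_y`` are zero for full detector exports (``origin:
    center``); region-of-interest sub-grids carry the offset of their own
    geometric center from the beam axis.
    """

    values: np.ndarray
    spacing_mm: float
    origin: str = "center"
    room: str = ""
    date: _dt.date | None = None
    interpolated: bool = False
    center_x: float = 0.0
    center_y: float = 0.0
    clipped: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D matrix")
        rows, cols = self.values.shape
        if rows < 2 or cols < 2:
            raise ValueError(f"grid must be at least 2x2, got {rows}x{cols}")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")
        if self.origin != "center":
            raise ValueError("only origin 'center' is supported")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    def x_coords(self) -> np.ndarray:
        """Pixel-center x coordinates (mm), increasing with column index."""
        j = np.arange(self.cols)
        return self.center_x + (j - (self.cols - 1) / 2) * self.spacing_mm

    def y_coords(self) -> np.ndarray:
        """Pixel-center y coordinates (mm), decreasing with row index."""
        i = np.arange(self.rows)
        return self.center_y + ((self.rows - 1) / 2 - i) * self.spacing_mm

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the pixel whose center is nearest (x, y)."""
        j = int(round((x - self.center_x) / self.spacing_mm + (self.cols - 1) / 2))
        i = int(round((self.rows - 1) / 2 - (y - self.center_y) / self.spacing_mm))
        return i, j


@dataclass
class Profile:
    """Dose samples along one axis at a fixed orthogonal coordinate."""

    positions: np.ndarray  # mm, strictly increasing
    doses: np.ndarray  # Gy
    axis: str  # "x" (left-right) or "y" (in-out)
    offset: float  # fixed coordinate of the orthogonal axis (mm)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.doses = np.asarray(self.doses, dtype=float)
        if self.positions.shape != self.doses.shape or self.positions.ndim != 1:
            raise ValueError("positions and doses must be equal-length 1D arrays")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")


def read_grid(path) -> DoseGrid:
    """Parse a DQA-GRID v1 file into a :class:`DoseGrid`."""
    with open(path, "r") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise GridParseError(f"line 1: expected '{_MAGIC}'")

    headers: dict[str, str] = {}
    i = 1
    while i < len(lines):
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        if ":" in line and not _looks_numeric_row(line):
            key, _, val = line.partition(":")
            key = key.strip().lower()
            if key in headers:
                raise GridParseError(f"line {i + 1}: duplicate header '{key}'")
            headers[key] = val.strip()
            i += 1
        else:
            break

    for req in ("rows", "cols", "spacing_mm", "units", "origin"):
        if req not in headers:
            raise GridParseError(f"missing required header '{req}'")
    if headers["units"] != "Gy":
        raise GridParseError(f"units must be 'Gy', got '{headers['units']}'")
    if headers["origin"] != "center":
        raise GridParseError(f"origin must be 'center', got '{headers['origin']}'")
    try:
        rows = int(headers["rows"])
        cols = int(headers["cols"])
        spacing = float(headers["spacing_mm"])
    except ValueError as exc:
        raise GridParseError(f"non-numeric header value: {exc}") from None

    matrix = []
    n_read = 0
    while i < len(lines) and n_read < rows:
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != cols:
            raise GridParseError(
                f"line {i}: expected {cols} values, got {len(parts)}"
            )
        try:
            matrix.append([float(p) for p in parts])
        except ValueError:
            raise GridParseError(f"line {i}: non-numeric dose value") from None
        n_read += 1
    if n_read != rows:
        raise GridParseError(f"expected {rows} matrix rows, found {n_read}")
    for line_no in range(i, len(lines)):
        if lines[line_no].strip() and not lines[line_no].strip().startswith("#"):
            raise GridParseError(f"line {line_no + 1}: extra data after matrix")

    date = None
    if headers.get("date"):
        date = _dt.date.fromisoformat(headers["date"])
    return DoseGrid(
        values=np.array(matrix, dtype=float),
        spacing_mm=spacing,
        room=headers.get("room", ""),
        date=date,
        interpolated=headers.get("interpolated", "false").lower() == "true",
    )


def _looks_numeric_row(line: str) -> bool:
    try:
        float(line.split()[0])
        return True
    except ValueError:
        return False


def write_grid(grid: DoseGrid, path) -> None:
    """Write a grid in the DQA-GRID v1 dialect at full float precision."""
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"rows: {grid.rows}\n")
        fh.write(f"cols: {grid.cols}\n")
        fh.write(f"spacing_mm: {float(grid.spacing_mm)!r}\n")
        fh.write("units: Gy\n")
        fh.write("origin: center\n")
        if grid.room:
            fh.write(f"room: {grid.room}\n")
        if grid.date is not None:
            fh.write(f"date: {grid.date.isoformat()}\n")
        fh.write(f"interpolated: {'true' if grid.interpolated else 'false'}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def resample(grid: DoseGrid, new_spacing_mm: float) -> DoseGrid:
    """Bilinearly resample onto a new symmetric pixel lattice.

    The new lattice is centered on the grid center (so it always contains a
    pixel exactly at the center) and extends as far as possible without
    stepping beyond the outermost native pixel centers — no extrapolation.
    The ``interpolated`` flag is set when the new pitch is finer than the
    current one.
    """
    if not new_spacing_mm > 0:
        raise ValueError("new_spacing_mm must be positive")
    half_x = (grid.cols - 1) / 2 * grid.spacing_mm
    half_y = (grid.rows - 1) / 2 * grid.spacing_mm
    eps = 1e-9
    nhx = int(np.floor(half_x / new_spacing_mm + eps))
    nhy = int(np.floor(half_y / new_spacing_mm + eps))
    if nhx < 1 or nhy < 1:
        raise ValueError("new spacing larger than the grid extent")

    xs = grid.x_coords()
    ys_asc = grid.y_coords()[::-1]
    interp = RegularGridInterpolator(
        (ys_asc, xs), grid.values[::-1, :], method="linear", bounds_error=True
    )
    new_x = grid.center_x + (np.arange(-nhx, nhx + 1)) * new_spacing_mm
    new_y_desc = grid.center_y + (np.arange(nhy, -nhy - 1, -1)) * new_spacing_mm
    np.clip(new_x, xs[0], xs[-1], out=new_x)
    np.clip(new_y_desc, ys_asc[0], ys_asc[-1], out=new_y_desc)
    gx, gy = np.meshgrid(new_x, new_y_desc)
    vals = interp(np.stack([gy.ravel(), gx.ravel()], axis=1)).reshape(gx.shape)
    return replace(
        grid,
        values=np.clip(vals, 0.0, None),
        spacing_mm=new_spacing_mm,
        interpolated=grid.interpolated or new_spacing_mm < grid.spacing_mm,
    )


def extract_roi(
    grid: DoseGrid,
    center_x: float,
    center_y: float,
    half_width_x: float,
    half_width_y: float,
    require_complete: bool = False,
) -> DoseGrid:
    """Sub-grid of all pixels whose centers lie in the closed rectangle.

    Coordinates of the returned grid remain relative to the beam axis.  A
    rectangle extending past the grid raises if ``require_complete``,
    otherwise returns the clipped sub-grid with ``clipped=True``.
    """
    eps = 1e-9 * grid.spacing_mm
    xs = grid.x_coords()
    ys = grid.y_coords()
    jmask = (xs >= center_x - half_width_x - eps) & (xs <= center_x + half_width_x + eps)
    imask = (ys >= center_y - half_width_y - eps) & (ys <= center_y + half_width_y + eps)
    if not jmask.any() or not imask.any():
        raise ValueError("requested ROI lies wholly outside the grid")
    out_of_bounds = (
        center_x - half_width_x < xs[0] - eps
        or center_x + half_width_x > xs[-1] + eps
        or center_y - half_width_y < ys[-1] - eps
        or center_y + half_width_y > ys[0] + eps
    )
    if out_of_bounds and require_complete:
        raise ValueError("requested ROI extends beyond the grid")
    if out_of_bounds:
        warnings.warn("ROI clipped at the grid edge", stacklevel=2)
    ii = np.where(imask)[0]
    jj = np.where(jmask)[0]
    sub = grid.values[ii[0] : ii[-1] + 1, jj[0] : jj[-1] + 1]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise ValueError("ROI smaller than 2x2 pixels")
    return replace(
        grid,
        values=sub.copy(),
        center_x=(xs[jj[0]] + xs[jj[-1]]) / 2,
        center_y=(ys[ii[0]] + ys[ii[-1]]) / 2,
        clipped=bool(out_of_bounds),
    )


def central_profiles(
    grid: DoseGrid, center_x: float = 0.0, center_y: float = 0.0
) -> tuple[Profile, Profile]:
    """Dose profiles through the row/column nearest the requested center.

    The x-profile is the row nearest ``center_y``; the y-profile is the
    column nearest ``center_x``.  Nearest-line selection only — no
    interpolation across rows or columns.
    """
    xs = grid.x_coords()
    ys = grid.y_coords()
    half = grid.spacing_mm / 2 + 1e-9
    if not (xs[0] - half <= center_x <= xs[-1] + half):
        raise ValueError("center_x outside grid")
    if not (ys[-1] - half <= center_y <= ys[0] + half):
        raise ValueError("center_y outside grid")
    i, j = grid.index_of(center_x, center_y)
    i = int(np.clip(i, 0, grid.rows - 1))
    j = int(np.clip(j, 0, grid.cols - 1))
    x_prof = Profile(positions=xs, doses=grid.values[i, :].copy(), axis="x", offset=ys[i])
    y_prof = Profile(
        positions=ys[::-1], doses=grid.values[::-1, j].copy(), axis="y", offset=xs[j]
    )
    return x_prof, y_prof
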