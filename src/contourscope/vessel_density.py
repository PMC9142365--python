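"""Grid-crossing microvessel density, as used in capillaroscopy.

Small-vessel density is measured by superimposing a grid of line segments
(by default 2 mm of horizontal plus 2 mm of vertical lines) on an image of
the mucosal microvasculature, counting how many times vessels thinner than
20 um cross the grid, and dividing by the total grid length.  Counting
operates on traced centreline polylines, matching the manual procedure;
automatic segmentation is out of scope.

Conventions (the source procedure is silent on degenerate contacts):
a transversal crossing counts 1, including one that passes exactly through
a vertex on the line; a polyline that merely touches a grid line and
retreats counts 0; a segment collinear with a grid line contributes 1 per
(vessel, grid line) pair regardless of overlap length.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "Vessel",
    "VesselSet",
    "GridSpec",
    "default_grid",
    "count_grid_crossings",
    "vessel_density",
    "aggregate_density",
    "read_vessel_csv",
    "write_vessel_csv",
]


@dataclass(frozen=True)
class Vessel:
    """A traced vessel: centreline polyline (y_um, x_um rows) and diameter."""

    polyline_um: np.ndarray  # (N, 2) as (y, x) in micrometres
    diameter_um: float

    def __post_init__(self) -> None:
        p = np.asarray(self.polyline_um, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 2:
            raise InvalidArgumentError("polyline must be (N>=2, 2)")
        if self.diameter_um <= 0:
            raise InvalidArgumentError("diameter must be positive")
        object.__setattr__(self, "polyline_um", p)


@dataclass(frozen=True)
class VesselSet:
    vessels: list[Vessel] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.vessels)


@dataclass(frozen=True)
class GridSpec:
    """Counting grid: horizontal segments (y, x0, x1) and vertical (x, y0, y1), in um."""

    horizontal_lines: tuple[tuple[float, float, float], ...]
    vertical_lines: tuple[tuple[float, float, float], ...]

    @property
    def total_length_mm(self) -> float:
        h = sum(abs(x1 - x0) for _, x0, x1 in self.horizontal_lines)
        v = sum(abs(y1 - y0) for _, y0, y1 in self.vertical_lines)
        return (h + v) / 1000.0


def default_grid(extent_mm: tuple[float, float] = (1.0, 1.0)) -> GridSpec:
    """Two 1 mm horizontal and two 1 mm vertical lines (4 mm total), centred."""
    ex, ey = extent_mm[0] * 1000.0, extent_mm[1] * 1000.0
    x0 = max((ex - 1000.0) / 2.0, 0.0)
    y0 = max((ey - 1000.0) / 2.0, 0.0)
    return GridSpec(
        horizontal_lines=((ey / 3.0, x0, x0 + 1000.0), (2.0 * ey / 3.0, x0, x0 + 1000.0)),
        vertical_lines=((ex / 3.0, y0, y0 + 1000.0), (2.0 * ex / 3.0, y0, y0 + 1000.0)),
    )


def _crossings_one_line(poly: np.ndarray, coord_idx: int, level: float, lo: float, hi: float) -> int:
    """Transversal crossings of one polyline with one axis-aligned segment.

    ``coord_idx`` selects the coordinate compared against ``level`` (0 = y
    for horizontal lines); the crossing point's other coordinate must land
    in [lo, hi].  A run of vertices exactly on the line is collapsed: it
    counts as one crossing when the flanking signs differ (pass-through) and
    zero when they agree (touch); a collinear run of positive length
    overlapping the segment adds one regardless.
    """
    lo, hi = min(lo, hi), max(lo, hi)
    c = poly[:, coord_idx]
    other = poly[:, 1 - coord_idx]
    signs = np.sign(c - level).astype(int)
    n = len(poly)

    collinear = False
    for i in range(n - 1):
        if signs[i] == 0 and signs[i + 1] == 0:
            a, b = sorted((other[i], other[i + 1]))
            if b >= lo and a <= hi and b > a:
                collinear = True
                break

    count = 0
    i = 0
    while i < n - 1:
        s0, s1 = signs[i], signs[i + 1]
        if s0 != 0 and s1 != 0:
            if s0 != s1:
                t = (level - c[i]) / (c[i + 1] - c[i])
                pos = other[i] + t * (other[i + 1] - other[i])
                if lo <= pos <= hi:
                    count += 1
            i += 1
            continue
        if s1 == 0 and s0 != 0:
            # entering a zero run: find its end and the sign on the far side
            j = i + 1
            while j < n and signs[j] == 0:
                j += 1
            if j < n and signs[j] != s0:
                run = other[i + 1 : j]
                if np.any((run >= lo) & (run <= hi)):
                    count += 1
            i = j if j > i + 1 else i + 1
            continue
        i += 1  # polyline starts on the line, or other degenerate step
    return count + (1 if collinear else 0)


def count_grid_crossings(vessels: VesselSet, grid: GridSpec, diameter_limit_um: float = 20.0) -> int:
    """Total grid crossings by vessels with diameter strictly below the limit.

    A vessel crossing k grid lines contributes k; multiple transversal
    crossings of the same line each count.
    """
    total = 0
    for v in vessels.vessels:
        if v.diameter_um >= diameter_limit_um:
            continue
        for y, x0, x1 in grid.horizontal_lines:
            total += _crossings_one_line(v.polyline_um, 0, y, x0, x1)
        for x, y0, y1 in grid.vertical_lines:
            total += _crossings_one_line(v.polyline_um, 1, x, y0, y1)
    return total


def vessel_density(
    crossings: int | VesselSet,
    grid: GridSpec,
    diameter_limit_um: float = 20.0,
) -> float:
    """Small-vessel density: grid crossings divided by total grid length (per mm)."""
    length = grid.total_length_mm
    if length <= 0:
        raise InvalidArgumentError("grid length must be positive")
    if isinstance(crossings, VesselSet):
        crossings = count_grid_crossings(crossings, grid, diameter_limit_um)
    return crossings / length


def aggregate_density(per_region_per_rater: list[list[float]]) -> tuple[float, float]:
    """Average densities over raters within each region, then over regions.

    Returns (mean, s.e.m. over regions); s.e.m. uses the sample standard
    deviation (ddof=1) and is 0 for a single region.
    """
    if not per_region_per_rater:
        raise InvalidArgumentError("need at least one region")
    region_means = np.array([float(np.mean(r)) for r in per_region_per_rater])
    mean = float(region_means.mean())
    if len(region_means) < 2:
        return mean, 0.0
    sem = float(region_means.std(ddof=1) / np.sqrt(len(region_means)))
    return mean, sem


def write_vessel_csv(vessels: VesselSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["vessel_id", "vertex_index", "x_um", "y_um", "diameter_um"])
        for vid, v in enumerate(vessels.vessels):
            for k, (y, x) in enumerate(v.polyline_um):
                writer.writerow([vid, k, f"{x:.6g}", f"{y:.6g}", f"{v.diameter_um:.6g}"])


def read_vessel_csv(path: str | Path) -> VesselSet:
    rows: dict[int, list[tuple[int, float, float, float]]] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            vid = int(rec["vessel_id"])
            rows.setdefault(vid, []).append(
                (int(rec["vertex_index"]), float(rec["y_um"]), float(rec["x_um"]), float(rec["diameter_um"]))
            )
    vessels = []
    for vid in sorted(rows):
        pts = sorted(rows[vid])
        poly = np.array([[y, x] for _, y, x, _ in pts])
        vessels.append(Vessel(polyline_um=poly, diameter_um=pts[0][3]))
    return VesselSet(vessels=vessels)
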