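"""Laser toolpath planning for the two sampling modes.

Raster mode (connected tissue, e.g. onion epidermis): ablate the cell interior
with horizontal serpentine scan lines clipped to the boundary inset inward by
a stand-off, so no waypoint disturbs adjacent cells.

Cut-and-drop mode (dispersed cells on PEN membrane): puncture the cell at its
centre of mass, cut a closed contour offset outward from the cell outline
(repeated passes to get through the membrane), then eject the dissected disc
into the capture probe with a final shot at the centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, MultiPolygon, Point, Polygon
from shapely.ops import unary_union

from .recognition import CellBoundary

DEFAULT_SPACING = 5.0  # µm, laser spot diameter
DEFAULT_INSET = 2.0  # µm stand-off inside the cell outline (raster)
DEFAULT_CUT_MARGIN = 3.0  # µm clearance outside the cell outline (CnD)
DEFAULT_N_PASSES = 2  # cut passes through the 4 µm PEN membrane


@dataclass
class LaserPath:
    """An ordered waypoint sequence for one cell, in stage µm."""

    cell_id: int
    mode: str  # "raster" | "cut"
    waypoints: list[tuple[float, float]]
    puncture_point: tuple[float, float] | None = None
    eject_point: tuple[float, float] | None = None
    n_passes: int = 1
    line_spacing: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("raster", "cut"):
            raise ValueError("mode must be 'raster' or 'cut'")
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")
        if self.mode == "raster" and (self.puncture_point or self.eject_point):
            raise ValueError("raster paths carry no puncture/eject points")
        if self.mode == "cut" and (self.puncture_point is None or self.eject_point is None):
            raise ValueError("cut paths require puncture and eject points")

    @property
    def reference_point(self) -> tuple[float, float]:
        """Representative location of the path (mean waypoint), for tour ordering."""
        pts = np.asarray(self.waypoints, dtype=float)
        return (float(pts[:, 0].mean()), float(pts[:, 1].mean()))


class CellTooSmallError(ValueError):
    """The cell is thinner than twice the requested inset; no raster fits."""


def raster_path(
    cell: CellBoundary, spacing: float = DEFAULT_SPACING, inset: float = DEFAULT_INSET
) -> LaserPath:
    """Horizontal serpentine raster of the cell interior.

    Scan lines run at y = y_min + k*spacing (k = 0, 1, ...) across the polygon
    inset inward by ``inset`` µm, linked in boustrophedon order (alternate rows
    reversed). Every waypoint lies strictly inside the original cell outline.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if inset < 0:
        raise ValueError("inset must be non-negative")
    region = cell.polygon.buffer(-inset) if inset > 0 else cell.polygon
    if region.is_empty or region.area <= 0:
        raise CellTooSmallError(
            f"cell {cell.cell_id} is too small to raster at inset {inset} µm"
        )
    if isinstance(region, MultiPolygon):
        region = max(region.geoms, key=lambda g: g.area)
    x_lo, y_lo, x_hi, y_hi = region.bounds

    def chords(y: float) -> list[LineString]:
        line = LineString([(x_lo - 1.0, y), (x_hi + 1.0, y)])
        clipped = region.intersection(line)
        if clipped.geom_type == "LineString" and clipped.length > 0:
            return [clipped]
        if clipped.geom_type == "MultiLineString":
            return [s for s in clipped.geoms if s.length > 0]
        return []

    rows: list[tuple[float, list[LineString]]] = []
    k = 0
    while True:
        y = y_lo + k * spacing
        if y > y_hi + 1e-12:
            break
        segs = chords(y)
        if segs:
            rows.append((y, segs))
        k += 1
    # end caps: where the nominal line is tangent to the outline (zero-length
    # chord) or the last line stops short, insert one chord half a spacing in
    # so the dilated swath still covers the extreme slices
    if rows:
        y_first = rows[0][0]
        if y_first - y_lo > 0.5 * spacing:
            y_cap = min(y_first - 0.5 * spacing, 0.5 * (y_lo + y_first))
            segs = chords(y_cap)
            if segs:
                rows.insert(0, (y_cap, segs))
        y_last = rows[-1][0]
        if y_hi - y_last > 0.5 * spacing:
            segs = chords(y_hi - 0.5 * spacing)
            if segs:
                rows.append((y_hi - 0.5 * spacing, segs))
    waypoints: list[tuple[float, float]] = []
    for row, (y, segments) in enumerate(rows):
        segments = sorted(segments, key=lambda s: s.bounds[0])
        if row % 2 == 1:
            segments = segments[::-1]
        for seg in segments:
            (xa, _), (xb, _) = seg.coords[0], seg.coords[-1]
            if row % 2 == 0:
                waypoints.extend([(min(xa, xb), y), (max(xa, xb), y)])
            else:
                waypoints.extend([(max(xa, xb), y), (min(xa, xb), y)])
    if not waypoints:
        # degenerate inset region narrower than one scan line
        c = region.centroid
        waypoints = [(float(c.x), float(c.y))]
    return LaserPath(
        cell_id=cell.cell_id,
        mode="raster",
        waypoints=waypoints,
        n_passes=1,
        line_spacing=spacing,
    )


def cut_contour(
    cell: CellBoundary,
    margin: float = DEFAULT_CUT_MARGIN,
    n_passes: int = DEFAULT_N_PASSES,
) -> LaserPath:
    """Closed cutting contour offset outward from the cell by ``margin`` µm.

    The offset uses round joins (16 arc segments per quadrant) so sharp
    vertices produce arcs, not miter spikes. The waypoint loop is emitted
    ``n_passes`` times — one pass per cut repetition through the membrane.
    Puncture and eject points are both the cell's centre of mass.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    offset = cell.polygon.buffer(margin, quad_segs=16, join_style="round")
    if isinstance(offset, MultiPolygon):
        offset = max(offset.geoms, key=lambda g: g.area)
    if offset.is_empty or offset.geom_type != "Polygon":
        raise ValueError(f"could not offset cell {cell.cell_id} by {margin} µm")
    loop = [(float(x), float(y)) for x, y in offset.exterior.coords]
    center = puncture_point(cell)
    return LaserPath(
        cell_id=cell.cell_id,
        mode="cut",
        waypoints=loop * n_passes,
        puncture_point=center,
        eject_point=center,
        n_passes=n_passes,
    )


def puncture_point(cell: CellBoundary) -> tuple[float, float]:
    """Centre of mass (area centroid) of the cell polygon.

    For a non-convex outline whose centroid falls outside the polygon, the
    interior point nearest the centroid is returned instead.
    """
    poly = cell.polygon
    if poly.area <= 0:
        raise ValueError("degenerate polygon has no puncture point")
    c = poly.centroid
    if poly.contains(c):
        return (float(c.x), float(c.y))
    # nearest interior point: project onto a slightly eroded polygon so the
    # result is strictly inside, not on the boundary
    eps = 1e-6 * math.sqrt(poly.area)
    interior = poly.buffer(-eps)
    if interior.is_empty:
        interior = poly
    target = interior.exterior.interpolate(interior.exterior.project(c)) \
        if not interior.contains(c) else c
    return (float(target.x), float(target.y))


def order_cells(paths: list[LaserPath], start: tuple[float, float] = (0.0, 0.0)) -> list[LaserPath]:
    """Greedy nearest-neighbour sampling tour over path reference points,
    starting from ``start``; ties broken by cell_id for determinism."""
    remaining = list(paths)
    ordered: list[LaserPath] = []
    cur = np.asarray(start, dtype=float)
    while remaining:
        best = min(
            remaining,
            key=lambda p: (
                float(np.hypot(*(np.asarray(p.reference_point) - cur))),
                p.cell_id,
            ),
        )
        ordered.append(best)
        remaining.remove(best)
        cur = np.asarray(best.reference_point)
    return ordered


def raster_coverage(cell: CellBoundary, path: LaserPath, inset: float = DEFAULT_INSET) -> float:
    """Fraction of the inset polygon's area covered by the scan segments
    dilated by half the line spacing (the laser spot radius)."""
    if path.mode != "raster" or path.line_spacing is None:
        raise ValueError("coverage is defined for raster paths")
    region = cell.polygon.buffer(-inset) if inset > 0 else cell.polygon
    if isinstance(region, MultiPolygon):
        region = max(region.geoms, key=lambda g: g.area)
    pts = path.waypoints
    segs = [
        LineString([pts[i], pts[i + 1]])
        for i in range(0, len(pts) - 1, 2)
    ]
    swath = unary_union([s.buffer(path.line_spacing / 2.0) for s in segs])
    return float(region.intersection(swath).area / region.area)


def tour_length(paths: list[LaserPath], start: tuple[float, float] = (0.0, 0.0)) -> float:
    """Total stage travel distance visiting the paths in the given order."""
    total = 0.0
    cur = np.asarray(start, dtype=float)
    for p in paths:
        ref = np.asarray(p.reference_point)
        total += float(np.hypot(*(ref - cur)))
        cur = ref
    return total
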