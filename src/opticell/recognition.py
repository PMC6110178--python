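"""Bright-field cell recognition: segment a slide image into individual cell
boundaries, filter by size / shape / isolation, and tile large regions into
microscope fields of view.

Coordinate convention (fixed for the whole pipeline): stage frame in µm with
x rightward and y downward, matching pixel axes; pixel indices are 0-based
with the origin at the image's top-left pixel centre. Boundary polygons are
oriented counter-clockwise (positive shoelace area) in that frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient
from shapely.strtree import STRtree
from skimage import filters, measure, morphology, segmentation

# Size/shape presets for the two study systems: ~10 µm algae and ~150 µm
# elongated onion epidermis cells.
PRESETS = {
    "algae": {"min_area": 20.0, "max_area": 700.0, "min_circularity": 0.5},
    "onion": {"min_area": 2000.0, "max_area": 1e6, "min_circularity": 0.2},
}


@dataclass
class OpticalImage:
    """A grayscale bright-field image with its stage-frame placement."""

    data: np.ndarray
    pixel_size: float  # µm per pixel
    stage_offset: tuple[float, float] = (0.0, 0.0)  # stage µm of pixel (0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("image must be a non-empty 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.any(np.asarray(self.data, dtype=float) < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class CellBoundary:
    """One recognized cell: closed polygon (µm, stage frame, CCW) + shape stats."""

    cell_id: int
    polygon: Polygon
    centroid: tuple[float, float] = field(init=False)
    area: float = field(init=False)
    equivalent_diameter: float = field(init=False)
    circularity: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ValueError("boundary polygon must be a valid non-empty polygon")
        self.polygon = orient(self.polygon, sign=1.0)  # CCW: positive shoelace area
        self.area = float(self.polygon.area)
        if self.area <= 0:
            raise ValueError("boundary polygon must enclose positive area")
        c = self.polygon.centroid
        self.centroid = (float(c.x), float(c.y))
        self.equivalent_diameter = 2.0 * math.sqrt(self.area / math.pi)
        perim = self.polygon.length
        self.circularity = min(1.0, 4.0 * math.pi * self.area / perim**2)


@dataclass
class FieldOfView:
    """One tile of a slide-scanning plan (stage rectangle, µm)."""

    row: int
    col: int
    x_min: float
    y_min: float
    x_max: float
    y_max: float


def pixel_to_stage(
    point: tuple[float, float], image: OpticalImage, check_bounds: bool = True
) -> tuple[float, float]:
    """Map a (col, row) pixel coordinate to stage µm."""
    col, row = point
    h, w = image.data.shape
    if check_bounds and not (0 <= col <= w - 1 and 0 <= row <= h - 1):
        raise ValueError(f"pixel {point} outside image bounds {(w, h)}")
    ox, oy = image.stage_offset
    return (ox + col * image.pixel_size, oy + row * image.pixel_size)


def stage_to_pixel(point: tuple[float, float], image: OpticalImage) -> tuple[float, float]:
    """Inverse of :func:`pixel_to_stage` (returns fractional (col, row))."""
    x, y = point
    ox, oy = image.stage_offset
    return ((x - ox) / image.pixel_size, (y - oy) / image.pixel_size)


def segment_cells(
    image: OpticalImage,
    min_area: float = PRESETS["algae"]["min_area"],
    max_area: float = PRESETS["algae"]["max_area"],
    min_circularity: float = PRESETS["algae"]["min_circularity"],
    background_flatten: bool = True,
    background_size: int = 35,
    simplify_tol_px: float = 0.5,
) -> list[CellBoundary]:
    """Segment dark elliptical cells on a bright background.

    Pipeline: grey-closing background estimate and subtraction (optional),
    Otsu threshold on the flattened image, morphological opening (disk radius
    0.2x the minimum expected cell radius), hole filling, 8-connected
    labeling, border-touching exclusion, then per-component polygonization of
    the outer contour with simplification. Components are kept only if their
    polygon area lies in [min_area, max_area] µm² and circularity
    (4*pi*A/P²) >= min_circularity. Cells are returned sorted by centroid
    (y, then x), ids assigned in that order.
    """
    if min_area >= max_area:
        raise ValueError("min_area must be smaller than max_area")
    if min_area <= 0:
        raise ValueError("min_area must be positive")
    img = np.asarray(image.data, dtype=float)
    if background_flatten:
        bg = ndimage.grey_closing(img, size=(background_size, background_size))
        signal = bg - img  # cells darker than background -> positive
    else:
        signal = img.max() - img
    if signal.max() <= signal.min():
        return []  # perfectly uniform image: no objects
    thr = filters.threshold_otsu(signal)
    mask = signal > thr
    min_radius_px = math.sqrt(min_area / math.pi) / image.pixel_size
    open_radius = max(1, int(round(0.2 * min_radius_px)))
    mask = morphology.opening(mask, morphology.disk(open_radius))
    mask = ndimage.binary_fill_holes(mask)
    mask = segmentation.clear_border(mask)
    labels = measure.label(mask, connectivity=2)
    boundaries: list[CellBoundary] = []
    for region in measure.regionprops(labels):
        poly = _region_polygon(region, labels, image, simplify_tol_px)
        if poly is None:
            continue
        if not (min_area <= poly.area <= max_area):
            continue
        circ = min(1.0, 4.0 * math.pi * poly.area / poly.length**2)
        if circ < min_circularity:
            continue
        boundaries.append(CellBoundary(cell_id=-1, polygon=poly))
    boundaries.sort(key=lambda b: (b.centroid[1], b.centroid[0]))
    for i, b in enumerate(boundaries):
        b.cell_id = i
    return boundaries


def _region_polygon(region, labels, image: OpticalImage, simplify_tol_px: float):
    """Outer contour of one labeled component as a simplified stage-frame polygon."""
    r0, c0, r1, c1 = region.bbox
    sub = np.pad((labels[r0:r1, c0:c1] == region.label).astype(float), 1)
    contours = measure.find_contours(sub, 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)  # outer ring has the most vertices
    rows = contour[:, 0] - 1 + r0
    cols = contour[:, 1] - 1 + c0
    ox, oy = image.stage_offset
    xs = ox + cols * image.pixel_size
    ys = oy + rows * image.pixel_size
    poly = Polygon(zip(xs, ys))
    if not poly.is_valid:
        poly = poly.buffer(0)
    poly = poly.simplify(simplify_tol_px * image.pixel_size)
    if poly.is_empty or poly.geom_type != "Polygon" or poly.area <= 0:
        return None
    return poly


def filter_isolated(cells: list[CellBoundary], margin: float) -> list[CellBoundary]:
    """Keep only cells with no neighbour intersecting their margin-dilated
    outline — the single-cell guarantee for cut-and-drop sampling.

    A cell survives iff no other cell's polygon intersects this cell's polygon
    dilated outward by ``margin`` µm. Monotone: growing the margin never adds
    cells back.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if len(cells) <= 1:
        return list(cells)
    tree = STRtree([c.polygon for c in cells])
    kept = []
    for i, cell in enumerate(cells):
        dilated = cell.polygon.buffer(margin)
        hits = [
            j
            for j in tree.query(dilated)
            if j != i and dilated.intersects(cells[j].polygon)
        ]
        if not hits:
            kept.append(cell)
    return kept


def tile_plan(
    region: tuple[float, float, float, float],
    fov_size: tuple[float, float],
    overlap: float = 0.0,
) -> list[FieldOfView]:
    """Tile a stage rectangle into overlapping fields of view in row-major
    serpentine order (even rows left-to-right, odd rows right-to-left).

    The step between tile origins is ``fov_size * (1 - overlap)``; the tile
    union always covers the region (the last row/column may extend past it).
    """
    x0, y0, x1, y1 = region
    w, h = fov_size
    if w <= 0 or h <= 0:
        raise ValueError("fov_size must be positive")
    if x1 <= x0 or y1 <= y0:
        raise ValueError("region must have positive extent")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    step_x, step_y = w * (1.0 - overlap), h * (1.0 - overlap)
    n_cols = 1 if x1 - x0 <= w else int(math.ceil((x1 - x0 - w) / step_x)) + 1
    n_rows = 1 if y1 - y0 <= h else int(math.ceil((y1 - y0 - h) / step_y)) + 1
    tiles = []
    for r in range(n_rows):
        cols = range(n_cols) if r % 2 == 0 else range(n_cols - 1, -1, -1)
        for c in cols:
            tx, ty = x0 + c * step_x, y0 + r * step_y
            tiles.append(FieldOfView(r, c, tx, ty, tx + w, ty + h))
    return tiles


def match_to_ground_truth(
    cells: list[CellBoundary],
    truth_centers: np.ndarray,
    tol: float = 2.0,
) -> list[tuple[int, int]]:
    """Greedy 1:1 matching of detected cells to true centres within ``tol`` µm.

    Returns (cell index, truth index) pairs; used for recall/precision scoring
    of the segmenter on synthetic scenes.
    """
    truth_centers = np.asarray(truth_centers, dtype=float)
    pairs = []
    for i, cell in enumerate(cells):
        d = np.hypot(
            truth_centers[:, 0] - cell.centroid[0],
            truth_centers[:, 1] - cell.centroid[1],
        )
        pairs.append((float(d.min(initial=np.inf)), i, int(d.argmin()) if d.size else -1))
    pairs.sort()
    used_cells, used_truth, matches = set(), set(), []
    for dist, i, j in pairs:
        if dist <= tol and i not in used_cells and j not in used_truth:
            matches.append((i, j))
            used_cells.add(i)
            used_truth.add(j)
    return matches
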