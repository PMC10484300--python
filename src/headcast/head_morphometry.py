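"""Head-outline morphometry: diameters, grid dedup filtering, agreement metrics.

The drone-side trait is the head diameter (HD): the longer side of the
minimum-area oriented bounding rectangle of a segmented head outline. Field
grids used for tiled segmentation introduce duplicates at shared edges, so
outlines touching a cell's bottom or right edge are dropped (each head then
survives in exactly one cell). Agreement between drone and field measurements
is summarised by r-squared of a simple linear regression and the RMSE of the
raw differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from shapely.geometry import LineString, MultiPoint, Polygon, box
from shapely.ops import unary_union

from .errors import DegenerateGeometryError, UndefinedMetricError


@dataclass
class HeadPolygon:
    """A head outline with its ground-truth identity and survey date.

    ``vertices`` are (x, y) pairs, geographic (metres) or pixel frame.
    """

    vertices: np.ndarray
    plant_id: int | None = None
    date: str | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise DegenerateGeometryError("polygon needs >= 3 (x, y) vertices")

    @property
    def shapely(self) -> Polygon:
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            poly = poly.buffer(0)
        return poly


def _as_polygon(polygon) -> Polygon:
    if isinstance(polygon, HeadPolygon):
        return polygon.shapely
    if isinstance(polygon, Polygon):
        return polygon
    return HeadPolygon(np.asarray(polygon, dtype=float)).shapely


def _vertex_array(polygon) -> np.ndarray:
    """Raw vertex coordinates of any accepted polygon representation.

    The convex hull of the vertex *set* is insensitive to ring ordering, so
    self-intersecting outlines from ragged segmentations measure the same as
    their repaired counterparts.
    """
    if isinstance(polygon, HeadPolygon):
        return polygon.vertices
    if isinstance(polygon, Polygon):
        return np.asarray(polygon.exterior.coords)[:-1]
    return np.asarray(polygon, dtype=float)


def min_area_rect_hd(polygon) -> float:
    """Longer side of the minimum-area oriented bounding rectangle.

    The convex hull is taken first (it leaves the minimum-area rectangle
    unchanged and stabilises ragged segmentation boundaries); shapely's
    rotating-calipers ``minimum_rotated_rectangle`` does the search.  Units
    follow the input coordinates.

    Raises
    ------
    DegenerateGeometryError
        For collinear / zero-area polygons.
    """
    hull = MultiPoint(_vertex_array(polygon)).convex_hull
    if hull.geom_type != "Polygon" or hull.area <= 0:
        raise DegenerateGeometryError("degenerate polygon: zero-area convex hull")
    rect = hull.minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)[:4]
    sides = np.hypot(*(np.diff(coords, axis=0, append=coords[:1]).T))
    return float(sides.max())


def min_area_rect_hd_batch(polygons) -> np.ndarray:
    """Vectorised :func:`min_area_rect_hd` over many polygons.

    Same convex-hull + minimum-rotated-rectangle route, through shapely's
    array API; used by the pipeline where thousands of outlines are measured
    per flight.
    """
    import shapely

    geoms = np.array([MultiPoint(_vertex_array(p)) for p in polygons], dtype=object)
    hulls = shapely.convex_hull(geoms)
    if np.any(shapely.area(hulls) <= 0):
        raise DegenerateGeometryError("degenerate polygon in batch: zero-area convex hull")
    rects = shapely.oriented_envelope(hulls)
    coords = shapely.get_coordinates(rects).reshape(len(geoms), 5, 2)
    sides = np.linalg.norm(np.diff(coords, axis=1), axis=2)  # (n, 4)
    return sides.max(axis=1)


def grid_filter(polygons, cell: tuple[float, float, float, float]) -> list:
    """Deduplicate tiled segmentation output within one grid cell.

    A polygon is retained iff it overlaps ``cell = (xmin, ymin, xmax,
    ymax)`` with positive area AND does not touch or cross the cell's bottom
    (y = ymin) or right (x = xmax) edge.  Bottom/right objects belong to the
    neighbouring cells; top/left objects are retained — so over a full
    tiling each head survives in exactly one cell (an edge-straddler is
    dropped where it touches bottom/right and kept in the neighbour, where
    it touches only top/left).  Coordinates are in the geographic frame
    (y increases northward; "bottom" is the southern edge).
    """
    xmin, ymin, xmax, ymax = cell
    cell_box = box(xmin, ymin, xmax, ymax)
    bottom = LineString([(xmin, ymin), (xmax, ymin)])
    right = LineString([(xmax, ymin), (xmax, ymax)])
    kept = []
    for p in polygons:
        geom = _as_polygon(p)
        if geom.intersection(cell_box).area <= 0:
            continue
        if geom.intersects(bottom) or geom.intersects(right):
            continue
        kept.append(p)
    return kept


def mid_iou(predicted, reference, cell: tuple[float, float, float, float]) -> float:
    """Intersection-over-union of two region sets clipped to a grid cell.

    Both the predicted and the reference regions are intersected with
    ``cell`` before the area IoU is computed, so segmentation quality is
    scored only inside the cell ("middle" IoU).  Empty-inside-cell on both
    sides is defined as 1.0; on one side only, 0.0.  Symmetric in its two
    region arguments.
    """
    cell_box = box(*cell)
    pred = unary_union([_as_polygon(p) for p in _iter_regions(predicted)]).intersection(cell_box)
    ref = unary_union([_as_polygon(p) for p in _iter_regions(reference)]).intersection(cell_box)
    union = pred.union(ref).area
    if union == 0:
        return 1.0 if (pred.is_empty or pred.area == 0) and (ref.is_empty or ref.area == 0) else 0.0
    return float(pred.intersection(ref).area / union)


def _iter_regions(regions):
    if isinstance(regions, (HeadPolygon, Polygon)) or (
        isinstance(regions, np.ndarray) and regions.ndim == 2
    ):
        return [regions]
    return list(regions)


def agreement_metrics(drone_mm, field_mm) -> tuple[float, float]:
    """(r-squared, RMSE) between drone and field head diameters.

    r-squared comes from ordinary least squares of the field values on the
    drone values; RMSE is on the raw differences, in the input units (mm).

    Raises
    ------
    UndefinedMetricError
        With fewer than 3 pairs or zero variance in the drone values.
    """
    x = np.asarray(drone_mm, dtype=float)
    y = np.asarray(field_mm, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UndefinedMetricError("paired 1-d arrays of equal length required")
    if len(x) < 3:
        raise UndefinedMetricError(f"need >= 3 pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise UndefinedMetricError("zero variance in the predictor (drone) values")
    fit = stats.linregress(x, y)
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    return float(fit.rvalue**2), rmse
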