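"""Positional plumbing for the tiled drone pipeline.

Large orthomosaics are split into square "sectors" small enough for
detection; each sector is extended by a buffer on its right and bottom edges
so heads straddling a boundary appear whole in at least one sector, and the
resulting duplicate detections are merged by non-maximum suppression.
Bounding-box centres become plant positions via a per-sector pixel-to-
geographic homography; ridges are recovered from the across-ridge position
histogram and plant IDs are assigned north-to-south within each ridge,
ridges west-to-east.

Conventions: pixel coordinates are 0-based with the origin at the top-left
and half-open windows; geographic coordinates are planar metres, x east,
y north.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    DegenerateLayoutError,
    EmptyWindowError,
    InvalidConfigError,
    InvalidDataError,
    ProjectionError,
)

#: Default square sector edge (pixels) for the detection stage.
DETECTION_SECTOR_PX = 1300
#: Default square crop edge (pixels) for the segmentation stage.
SEGMENTATION_SECTOR_PX = 1500
#: Default sector buffer (pixels), slightly larger than the biggest head.
SECTOR_BUFFER_PX = 200
#: Default square ROI around a seedling position (pixels).
HEAD_ROI_PX = 100


@dataclass(frozen=True)
class TilingConfig:
    """Square tiling of an image extent with a right/bottom buffer."""

    image_extent: tuple[int, int]  # (width, height) pixels
    sector_size: int = DETECTION_SECTOR_PX
    buffer: int = SECTOR_BUFFER_PX

    def __post_init__(self):
        w, h = self.image_extent
        if self.sector_size <= 0 or w <= 0 or h <= 0:
            raise InvalidConfigError("sector size and image extent must be positive")
        if self.buffer < 0 or self.buffer >= self.sector_size:
            raise InvalidConfigError("buffer must satisfy 0 <= buffer < sector_size")


@dataclass(frozen=True)
class SectorWindow:
    """One tile: core window (a partition cell) and its buffered extension."""

    sector_id: int
    core: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    buffered: tuple[int, int, int, int]


def tile_image(config: TilingConfig) -> list[SectorWindow]:
    """Tile the image extent into sectors.

    Core windows exactly partition the extent (half-open, 0-based, row-major
    order); each buffered window extends its core by ``buffer`` pixels on the
    right and bottom edges only, clipped at the extent — the L-shaped overlap
    that keeps boundary-straddling heads whole in one sector.
    """
    w, h = config.image_extent
    s, buf = config.sector_size, config.buffer
    windows = []
    sector_id = 0
    for y0 in range(0, h, s):
        for x0 in range(0, w, s):
            x1, y1 = min(x0 + s, w), min(y0 + s, h)
            bx1, by1 = min(x0 + s + buf, w), min(y0 + s + buf, h)
            windows.append(SectorWindow(sector_id, (x0, y0, x1, y1), (x0, y0, bx1, by1)))
            sector_id += 1
    return windows


@dataclass
class Detection:
    """A detector bounding box in its sector frame, with the sector origin."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    score: float = 1.0
    sector_id: int | None = None
    sector_origin: tuple[float, float] = (0.0, 0.0)
    plant_id: int | None = None  # ground-truth passthrough on synthetic data

    def __post_init__(self):
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise InvalidDataError(f"degenerate box {self.box_sector()}")

    def box_sector(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)

    def box_image(self) -> tuple[float, float, float, float]:
        ox, oy = self.sector_origin
        return (self.xmin + ox, self.ymin + oy, self.xmax + ox, self.ymax + oy)

    def center_image(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.box_image()
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


def box_iou(a: tuple, b: tuple) -> float:
    """Intersection-over-union of two (xmin, ymin, xmax, ymax) boxes."""
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(0.0, ix1 - ix0) * max(0.0, iy1 - iy0)
    if inter == 0.0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def nms_merge(detections: list[Detection], iou_threshold: float = 0.5) -> list[Detection]:
    """Greedy score-descending non-maximum suppression in the image frame.

    Keeps the highest-scoring box, suppresses every remaining box whose IoU
    with it exceeds ``iou_threshold``, and repeats.  Output is in descending
    score order; no two survivors overlap above the threshold.  Idempotent.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise InvalidConfigError("iou_threshold must lie strictly in (0, 1)")
    boxes = np.array([d.box_image() for d in detections], dtype=float).reshape(-1, 4)
    scores = np.array([d.score for d in detections], dtype=float)
    order = np.argsort(-scores, kind="stable")
    x0, y0, x1, y1 = boxes[order].T
    areas = (x1 - x0) * (y1 - y0)
    alive = np.ones(len(order), dtype=bool)
    survivors: list[int] = []
    for i in range(len(order)):
        if not alive[i]:
            continue
        survivors.append(order[i])
        ix0 = np.maximum(x0[i], x0[i + 1:])
        iy0 = np.maximum(y0[i], y0[i + 1:])
        ix1 = np.minimum(x1[i], x1[i + 1:])
        iy1 = np.minimum(y1[i], y1[i + 1:])
        inter = np.clip(ix1 - ix0, 0.0, None) * np.clip(iy1 - iy0, 0.0, None)
        iou = inter / (areas[i] + areas[i + 1:] - inter)
        alive[i + 1:] &= iou <= iou_threshold
    return [detections[i] for i in survivors]


class ProjectiveTransform:
    """3x3 homography mapping pixel coordinates to geographic coordinates."""

    def __init__(self, matrix):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (3, 3):
            raise InvalidConfigError("homography must be a 3x3 matrix")
        if abs(np.linalg.det(m)) < 1e-15:
            raise InvalidConfigError("homography matrix is singular")
        self.matrix = m

    @classmethod
    def identity(cls) -> "ProjectiveTransform":
        return cls(np.eye(3))

    @classmethod
    def scale_translate(cls, sx: float, sy: float, tx: float = 0.0, ty: float = 0.0):
        return cls(np.array([[sx, 0.0, tx], [0.0, sy, ty], [0.0, 0.0, 1.0]]))

    @property
    def inverse(self) -> "ProjectiveTransform":
        return ProjectiveTransform(np.linalg.inv(self.matrix))

    def apply(self, points) -> np.ndarray:
        """Map (n, 2) points through the homography (homogeneous division).

        Raises
        ------
        ProjectionError
            If any point maps to (or numerically near) the line at infinity.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        homog = np.column_stack([pts, np.ones(len(pts))])
        mapped = homog @ self.matrix.T
        w = mapped[:, 2]
        if np.any(np.abs(w) < 1e-12):
            raise ProjectionError("point maps to the line at infinity (w ~ 0)")
        out = mapped[:, :2] / w[:, None]
        return out if np.asarray(points).ndim == 2 else out[0]


def forward_project(pixel_geometry, transform: ProjectiveTransform):
    """Pixel-frame geometry (point array or HeadPolygon vertices) -> geographic."""
    return _project(pixel_geometry, transform)


def backward_project(geo_geometry, transform: ProjectiveTransform):
    """Geographic geometry -> pixel frame, via the inverse homography."""
    return _project(geo_geometry, transform.inverse)


def _project(geometry, transform: ProjectiveTransform):
    from .head_morphometry import HeadPolygon

    if isinstance(geometry, HeadPolygon):
        return HeadPolygon(
            transform.apply(geometry.vertices), plant_id=geometry.plant_id, date=geometry.date
        )
    return transform.apply(geometry)


def detections_to_positions(
    detections: list[Detection],
    transforms,
) -> np.ndarray:
    """Map bounding-box centres to geographic positions.

    ``transforms`` is either one ProjectiveTransform for the whole image
    frame or a mapping ``sector_id -> ProjectiveTransform`` (transforms that
    map image-frame pixels to geographic coordinates).

    Raises
    ------
    InvalidConfigError
        If a detection's sector has no transform.
    """
    points = []
    for det in detections:
        if isinstance(transforms, ProjectiveTransform):
            tf = transforms
        else:
            tf = transforms.get(det.sector_id)
            if tf is None:
                raise InvalidConfigError(f"no transform for sector {det.sector_id}")
        points.append(tf.apply(np.array(det.center_image())))
    return np.array(points).reshape(-1, 2)


#: Histogram bin width (m) for the across-ridge position distribution.
RIDGE_BIN_M = 0.1
#: Minimum peak separation as a fraction of the expected ridge spacing.
RIDGE_MIN_SEPARATION_FRAC = 0.7


def detect_ridges(positions, expected_spacing: float = 0.70) -> np.ndarray:
    """Assign a ridge index to every position from the east-west histogram.

    A histogram of the x (across-ridge) coordinate is built with 0.1 m bins;
    peaks separated by at least ``0.7 * expected_spacing`` define ridge
    centres, each position is assigned to its nearest centre, and indices
    are numbered west to east starting at 0.
    """
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(pts) == 0:
        raise DegenerateLayoutError("no positions given")
    x = pts[:, 0]
    if np.ptp(x) < RIDGE_MIN_SEPARATION_FRAC * expected_spacing:
        return np.zeros(len(x), dtype=int)  # single ridge
    edges = np.arange(x.min() - RIDGE_BIN_M, x.max() + 2 * RIDGE_BIN_M, RIDGE_BIN_M)
    counts, edges = np.histogram(x, bins=edges)
    padded = np.concatenate([[0], counts, [0]])  # so boundary ridges peak too
    min_dist = max(1, int(round(RIDGE_MIN_SEPARATION_FRAC * expected_spacing / RIDGE_BIN_M)))
    peaks, _ = find_peaks(padded, distance=min_dist)
    if len(peaks) == 0:
        raise DegenerateLayoutError("no ridge peak found in the position histogram")
    bin_centers = (edges[:-1] + edges[1:]) / 2.0
    raw_centers = bin_centers[peaks - 1]
    # refine each ridge center as the mean x of its assigned members
    assign = np.argmin(np.abs(x[:, None] - raw_centers[None, :]), axis=1)
    centers = np.array([x[assign == k].mean() if np.any(assign == k) else raw_centers[k]
                        for k in range(len(raw_centers))])
    order = np.argsort(centers)  # west -> east
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    return rank[assign]


def assign_ids(positions, ridge_indices) -> np.ndarray:
    """Assign consecutive plant IDs from 1.

    Primary sort: ridge index (west to east); secondary: northing descending
    (north to south); exact-position ties broken by easting.  The ID map is
    invariant to the input ordering of the positions.
    """
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    ridges = np.asarray(ridge_indices, dtype=int)
    if len(pts) != len(ridges):
        raise InvalidDataError("positions and ridge indices differ in length")
    order = np.lexsort((pts[:, 0], -pts[:, 1], ridges))
    ids = np.empty(len(pts), dtype=int)
    ids[order] = np.arange(1, len(pts) + 1)
    return ids


def crop_roi(
    position: tuple[float, float],
    roi_size: int = HEAD_ROI_PX,
    image_extent: tuple[int, int] | None = None,
) -> tuple[int, int, int, int]:
    """Square half-open pixel window centred at ``position``.

    Clipped at the image extent when one is given.

    Raises
    ------
    EmptyWindowError
        If the position lies outside the image.
    """
    if roi_size <= 0:
        raise InvalidConfigError("roi_size must be positive")
    cx, cy = position
    if image_extent is not None:
        w, h = image_extent
        if not (0 <= cx < w and 0 <= cy < h):
            raise EmptyWindowError(f"position {position} outside image extent {image_extent}")
    x0 = int(np.floor(cx - roi_size / 2.0))
    y0 = int(np.floor(cy - roi_size / 2.0))
    x1, y1 = x0 + roi_size, y0 + roi_size
    if image_extent is not None:
        w, h = image_extent
        x0, y0 = max(0, x0), max(0, y0)
        x1, y1 = min(w, x1), min(h, y1)
    else:
        x0, y0 = max(0, x0), max(0, y0)
    return (x0, y0, x1, y1)
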