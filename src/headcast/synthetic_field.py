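"""Virtual broccoli field with known ground truth.

Emulates the data a drone phenotyping pipeline would produce for a ridged
commercial broccoli field — rows 70 cm apart, plants at 35 cm intervals —
without any imagery: per-plant sigmoid-in-thermal-time head growth with
individual variation in head-induction timing, drone measurement noise with
systematic underestimation from leaf occlusion, head-outline polygons, and
seedling detections duplicated across buffered image sectors.  Every
generator is fully deterministic under a fixed seed.

Individual variation is a per-plant shift ``delta_T0 ~ Normal(0, sigma_T)``
on the thermal-time axis (default sigma_T = 30 degC-day): plants that induce
heads earlier sit further along the shared growth curve.  Drone observations
apply a multiplicative occlusion factor beta <= 1 plus additive Gaussian
noise; manual field observations apply (smaller) noise only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .field_geometry import Detection, ProjectiveTransform, TilingConfig, tile_image
from .growth_model import GrowthModelParams, TemperatureSeries, predict_hd
from .head_morphometry import HeadPolygon

# Monthly mean temperatures (degC) typical of the Tokyo-area growing seasons
# the generator emulates; daily values add AR(1) noise around these.
MONTHLY_MEANS_2020 = {3: 10.5, 4: 12.8, 5: 19.6, 6: 21.8}
MONTHLY_MEANS_2021 = {3: 12.5, 4: 15.0, 5: 19.7, 6: 22.1}


@dataclass(frozen=True)
class FieldLayout:
    """Ridged field layout in a local planar east/north metric frame.

    Either give ``n_ridges`` and ``plants_per_ridge`` (bounds derived), or
    set both to None and give ``field_bounds`` to fill the grid that fits.
    """

    n_ridges: int | None = 10
    plants_per_ridge: int | None = 74
    ridge_spacing: float = 0.70  # m between rows
    plant_spacing: float = 0.35  # m within a row
    position_jitter_sd: float = 0.03  # m
    origin: tuple[float, float] = (0.0, 0.0)  # geographic (x east, y north)
    field_bounds: tuple[float, float, float, float] | None = None

    def __post_init__(self):
        if self.ridge_spacing <= 0 or self.plant_spacing <= 0:
            raise InvalidConfigError("spacings must be positive")
        if self.position_jitter_sd < 0:
            raise InvalidConfigError("jitter sd must be nonnegative")
        if self.n_ridges is None or self.plants_per_ridge is None:
            if self.field_bounds is None:
                raise InvalidConfigError("grid size or field_bounds required")
        elif self.n_ridges < 1 or self.plants_per_ridge < 1:
            raise InvalidConfigError("need at least one ridge and one plant")

    def bounds(self) -> tuple[float, float, float, float]:
        if self.field_bounds is not None:
            return self.field_bounds
        ox, oy = self.origin
        margin = max(4.0 * self.position_jitter_sd, 0.05)
        width = (self.n_ridges - 1) * self.ridge_spacing
        depth = (self.plants_per_ridge - 1) * self.plant_spacing
        return (ox - margin, oy - depth - margin, ox + width + margin, oy + margin)


def generate_layout(layout: FieldLayout, seed: int) -> pd.DataFrame:
    """Plant positions on a jittered grid, with ridge index and truth ID.

    Returns a frame with ``plant_id`` (1..n, ridge-major west to east, north
    to south within a ridge), ``ridge``, ``x``, ``y``.  Jittered positions
    are clipped into the field bounds.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    ox, oy = layout.origin
    xmin, ymin, xmax, ymax = layout.bounds()
    if layout.n_ridges is not None:
        ridge_x = ox + np.arange(layout.n_ridges) * layout.ridge_spacing
        plant_y = oy - np.arange(layout.plants_per_ridge) * layout.plant_spacing
    else:
        # fill the grid of points falling inside the stated bounds
        ridge_x = np.arange(ox, xmax + 1e-9, layout.ridge_spacing)
        ridge_x = ridge_x[(ridge_x >= xmin) & (ridge_x <= xmax)]
        plant_y = np.arange(oy, ymin - 1e-9, -layout.plant_spacing)
        plant_y = plant_y[(plant_y >= ymin) & (plant_y <= ymax)]
        if len(ridge_x) == 0 or len(plant_y) == 0:
            raise InvalidConfigError("field_bounds admit no grid point")
    rows = []
    pid = 1
    for r, rx in enumerate(ridge_x):
        for py in plant_y:  # north -> south
            rows.append({"plant_id": pid, "ridge": r, "x": rx, "y": py})
            pid += 1
    frame = pd.DataFrame(rows)
    if layout.position_jitter_sd > 0:
        jitter = rng.normal(0.0, layout.position_jitter_sd, size=(len(frame), 2))
        frame["x"] = np.clip(frame["x"] + jitter[:, 0], xmin, xmax)
        frame["y"] = np.clip(frame["y"] + jitter[:, 1], ymin, ymax)
    return frame


@dataclass(frozen=True)
class GrowthTruthConfig:
    """Ground-truth growth and observation-noise parameters.

    The base curve defaults to the field-initialization parameters of a
    Tokyo-area Jet dome broccoli season; ``delta_t0_sd`` spreads individuals
    along the thermal-time axis; ``beta`` is the drone occlusion factor
    (drone observations never systematically overestimate); noise sds are in
    millimetres.  ``east_shift_days`` delays the season start of plants east
    of the field midline, emulating a split-transplant trial.
    """

    a: float = 5.53
    b: float = 2.05
    c: float = 0.00546
    delta_t0_sd: float = 30.0  # degC-day
    beta: float = 0.95
    drone_noise_sd_mm: float = 5.0
    field_noise_sd_mm: float = 2.0
    season_start: str = "2020-03-20"
    east_shift_days: int = 0

    def __post_init__(self):
        if not (0.0 < self.beta <= 1.0):
            raise InvalidConfigError("occlusion factor beta must lie in (0, 1]")
        if self.delta_t0_sd < 0 or self.drone_noise_sd_mm < 0 or self.field_noise_sd_mm < 0:
            raise InvalidConfigError("spread / noise sds must be nonnegative")
        GrowthModelParams(self.a, self.b, self.c)  # validates positivity

    @property
    def params(self) -> GrowthModelParams:
        return GrowthModelParams(self.a, self.b, self.c)


def make_growth_truth(layout_df: pd.DataFrame, config: GrowthTruthConfig, seed: int) -> pd.DataFrame:
    """Attach per-plant growth truth to a layout table.

    Adds columns ``a``, ``b``, ``c``, ``delta_T0`` (degC-day, zero-mean
    normal) and ``season_start`` (per-cohort when ``east_shift_days`` != 0).
    """
    rng = np.random.default_rng(seed)
    truth = layout_df.copy()
    n = len(truth)
    truth["a"] = config.a
    truth["b"] = config.b
    truth["c"] = config.c
    truth["delta_T0"] = rng.normal(0.0, config.delta_t0_sd, size=n) if config.delta_t0_sd else 0.0
    start = pd.Timestamp(config.season_start)
    truth["season_start"] = start.strftime("%Y-%m-%d")
    if config.east_shift_days:
        midline = (truth["x"].min() + truth["x"].max()) / 2.0
        east = truth["x"] > midline
        shifted = (start + pd.Timedelta(days=config.east_shift_days)).strftime("%Y-%m-%d")
        truth.loc[east, "season_start"] = shifted
    return truth


def simulate_growth(
    truth: pd.DataFrame,
    config: GrowthTruthConfig,
    temps: TemperatureSeries,
    dates,
    seed: int,
) -> pd.DataFrame:
    """Noise-free trajectories plus noisy drone and field observations.

    Per plant and date, with T the clipped temperature sum from the plant's
    season start: ``true_HD = exp(a - b * exp(-c * (T + delta_T0)))``;
    ``drone_HD = beta * true_HD + Normal(0, drone sd)`` (truncated at 0);
    ``field_HD = true_HD + Normal(0, field sd)`` (truncated at 0).

    Raises :class:`~headcast.errors.MissingDataError` if a date is outside
    the temperature series.
    """
    rng = np.random.default_rng(seed)
    date_index = pd.DatetimeIndex(pd.to_datetime(list(dates))).normalize()
    # signed temperature sum per (season_start, date); dates before the
    # season start sit at negative T
    starts = truth["season_start"].unique()
    t_base = {
        (s, d): (temps.clipped_sum(s, d) if d >= pd.Timestamp(s) else -temps.clipped_sum(d, s))
        for s in starts
        for d in date_index
    }
    n_plants, n_dates = len(truth), len(date_index)
    base = np.array(
        [[t_base[(s, d)] for d in date_index] for s in truth["season_start"]]
    )  # (n_plants, n_dates)
    t_eff = base + truth["delta_T0"].to_numpy()[:, None]
    a = truth["a"].to_numpy()[:, None]
    b = truth["b"].to_numpy()[:, None]
    c = truth["c"].to_numpy()[:, None]
    true_hd = np.exp(a - b * np.exp(-c * t_eff))
    obs = pd.DataFrame(
        {
            "plant_id": np.repeat(truth["plant_id"].to_numpy(), n_dates),
            "date": np.tile(date_index.strftime("%Y-%m-%d"), n_plants),
            "true_hd_mm": true_hd.ravel(),
        }
    )
    n = len(obs)
    drone_noise = rng.normal(0.0, config.drone_noise_sd_mm, n) if config.drone_noise_sd_mm else 0.0
    field_noise = rng.normal(0.0, config.field_noise_sd_mm, n) if config.field_noise_sd_mm else 0.0
    obs["drone_hd_mm"] = np.maximum(0.0, config.beta * obs["true_hd_mm"] + drone_noise)
    obs["field_hd_mm"] = np.maximum(0.0, obs["true_hd_mm"] + field_noise)
    return obs


def synth_temperatures(
    start,
    end,
    monthly_means: dict[int, float] | None = None,
    ar1_rho: float = 0.7,
    daily_sd: float = 2.0,
    seed: int = 0,
) -> TemperatureSeries:
    """Daily mean temperatures: monthly means plus AR(1) daily anomalies.

    ``daily_sd`` is the stationary standard deviation of the anomaly
    process; ``monthly_means`` maps month number to mean degC (defaults to a
    2020-like Tokyo season).
    """
    means = monthly_means or MONTHLY_MEANS_2020
    rng = np.random.default_rng(seed)
    idx = pd.date_range(pd.Timestamp(start), pd.Timestamp(end), freq="D")
    base = np.array([means.get(d.month, np.nan) for d in idx])
    if np.any(np.isnan(base)):
        missing = sorted({d.month for d in idx if d.month not in means})
        raise InvalidConfigError(f"no monthly mean for month(s) {missing}")
    anom = np.empty(len(idx))
    innov_sd = daily_sd * np.sqrt(1.0 - ar1_rho**2)
    anom[0] = rng.normal(0.0, daily_sd)
    for i in range(1, len(idx)):
        anom[i] = ar1_rho * anom[i - 1] + rng.normal(0.0, innov_sd)
    return TemperatureSeries(idx, base + anom)


# ---------------------------------------------------------------------------
# Sector transforms, polygons, detections
# ---------------------------------------------------------------------------

#: Default ground sampling distance, m per pixel (15 m flight height class).
DEFAULT_GSD_M = 0.004
#: Default seedling footprint (m) used for detection bounding boxes.
SEEDLING_BOX_M = 0.20


def build_sector_transforms(
    tiling: TilingConfig,
    gsd_m: float = DEFAULT_GSD_M,
    geo_origin: tuple[float, float] = (0.0, 0.0),
) -> dict[int, ProjectiveTransform]:
    """Per-sector homographies from image-frame pixels to geographic metres.

    The image origin (top-left) maps to ``geo_origin`` with x increasing
    east and pixel rows increasing southward (y north decreases).
    """
    ox, oy = geo_origin
    matrix = np.array([[gsd_m, 0.0, ox], [0.0, -gsd_m, oy], [0.0, 0.0, 1.0]])
    return {w.sector_id: ProjectiveTransform(matrix) for w in tile_image(tiling)}


def emit_polygons_and_detections(
    observations: pd.DataFrame,
    layout_df: pd.DataFrame,
    tiling: TilingConfig,
    transforms: dict[int, ProjectiveTransform],
    seed: int,
    n_vertices: int = 64,
    vertex_noise_frac: float = 0.02,
    seedling_box_m: float = SEEDLING_BOX_M,
) -> tuple[list[HeadPolygon], list[Detection]]:
    """Head polygons per observation and seedling detections per sector.

    Each observation yields one geographic-frame polygon: a regular
    ``n_vertices``-gon of circumdiameter ``drone_hd_mm`` with relative radial
    vertex noise, centred on the plant — so the minimum-area-rectangle HD of
    the polygon recovers ``drone_hd_mm`` up to the vertex-noise tolerance.

    Each plant yields one detection bounding box (seedling footprint, fixed
    size) in every sector whose *buffered* window contains it, so plants
    inside buffer-overlap zones are emitted two or more times — the
    duplication NMS must later remove.  Ground-truth ``plant_id`` is attached
    to every emitted object; a plant outside all sectors is skipped with a
    warning.
    """
    rng = np.random.default_rng(seed)
    windows = tile_image(tiling)
    pos = layout_df.set_index("plant_id")[["x", "y"]]

    # --- detections -------------------------------------------------------
    detections: list[Detection] = []
    plant_ids = pos.index.to_numpy()
    geo_pts = pos[["x", "y"]].to_numpy()
    emitted = np.zeros(len(plant_ids), dtype=int)
    for w in windows:
        tf = transforms[w.sector_id]
        pix = tf.inverse.apply(geo_pts)
        bx0, by0, bx1, by1 = w.buffered
        inside = (pix[:, 0] >= bx0) & (pix[:, 0] < bx1) & (pix[:, 1] >= by0) & (pix[:, 1] < by1)
        scale = np.linalg.norm(tf.matrix[:2, 0])  # m per pixel along x
        half = seedling_box_m / scale / 2.0
        for k in np.flatnonzero(inside):
            px, py = pix[k]
            detections.append(
                Detection(
                    xmin=px - w.core[0] - half,
                    ymin=py - w.core[1] - half,
                    xmax=px - w.core[0] + half,
                    ymax=py - w.core[1] + half,
                    score=float(rng.uniform(0.6, 0.99)),
                    sector_id=w.sector_id,
                    sector_origin=(float(w.core[0]), float(w.core[1])),
                    plant_id=int(plant_ids[k]),
                )
            )
            emitted[k] += 1
    for k in np.flatnonzero(emitted == 0):
        warnings.warn(f"plant {plant_ids[k]} lies outside all sectors; skipped", stacklevel=2)

    # --- polygons ---------------------------------------------------------
    inside = set(d.plant_id for d in detections)
    polygons: list[HeadPolygon] = []
    angles = np.arange(n_vertices) * (2.0 * np.pi / n_vertices)
    centers = {int(pid): (float(x), float(y)) for pid, x, y in
               zip(plant_ids, geo_pts[:, 0], geo_pts[:, 1])}
    for row in observations.itertuples():
        plant_id = int(row.plant_id)
        if plant_id not in inside:
            continue
        gx, gy = centers[plant_id]
        radius_m = float(row.drone_hd_mm) / 2.0 / 1000.0
        if radius_m <= 0:
            continue
        theta = angles + rng.uniform(0.0, 2.0 * np.pi / n_vertices)
        radial = radius_m * (
            1.0 + (rng.normal(0.0, vertex_noise_frac, n_vertices) if vertex_noise_frac else 0.0)
        )
        verts = np.column_stack([gx + radial * np.cos(theta), gy + radial * np.sin(theta)])
        polygons.append(HeadPolygon(verts, plant_id=plant_id, date=str(row.date)))
    return polygons, detections


def count_buffer_overlap_plants(
    layout_df: pd.DataFrame,
    tiling: TilingConfig,
    transforms: dict[int, ProjectiveTransform],
) -> int:
    """Number of plants lying in >= 2 buffered sector windows (by construction)."""
    windows = tile_image(tiling)
    pts = layout_df[["x", "y"]].to_numpy()
    hits = np.zeros(len(pts), dtype=int)
    for w in windows:
        pix = transforms[w.sector_id].inverse.apply(pts)
        bx0, by0, bx1, by1 = w.buffered
        hits += (
            (pix[:, 0] >= bx0) & (pix[:, 0] < bx1) & (pix[:, 1] >= by0) & (pix[:, 1] < by1)
        ).astype(int)
    return int(np.sum(hits >= 2))


# ---------------------------------------------------------------------------
# Plain-text readers / writers (CSV, GeoJSON, JSON sidecars)
# ---------------------------------------------------------------------------


def write_polygons_geojson(polygons: list[HeadPolygon], path) -> None:
    features = []
    for p in polygons:
        ring = [[float(x), float(y)] for x, y in p.vertices]
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"plant_id": p.plant_id, "date": p.date},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_polygons_geojson(path) -> list[HeadPolygon]:
    with open(path) as fh:
        collection = json.load(fh)
    polygons = []
    for feat in collection["features"]:
        ring = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)[:-1]
        props = feat.get("properties", {})
        polygons.append(HeadPolygon(ring, plant_id=props.get("plant_id"), date=props.get("date")))
    return polygons


def write_detections_csv(detections: list[Detection], path) -> None:
    pd.DataFrame(
        [
            {
                "sector_id": d.sector_id,
                "sector_origin_x": d.sector_origin[0],
                "sector_origin_y": d.sector_origin[1],
                "xmin": d.xmin,
                "ymin": d.ymin,
                "xmax": d.xmax,
                "ymax": d.ymax,
                "score": d.score,
                "plant_id": d.plant_id,
            }
            for d in detections
        ]
    ).to_csv(path, index=False)


def read_detections_csv(path) -> list[Detection]:
    frame = pd.read_csv(path)
    return [
        Detection(
            xmin=r.xmin,
            ymin=r.ymin,
            xmax=r.xmax,
            ymax=r.ymax,
            score=r.score,
            sector_id=int(r.sector_id),
            sector_origin=(r.sector_origin_x, r.sector_origin_y),
            plant_id=None if pd.isna(r.plant_id) else int(r.plant_id),
        )
        for r in frame.itertuples()
    ]


def write_transforms_json(transforms: dict[int, ProjectiveTransform], path) -> None:
    with open(path, "w") as fh:
        json.dump({str(k): tf.matrix.tolist() for k, tf in transforms.items()}, fh)


def read_transforms_json(path) -> dict[int, ProjectiveTransform]:
    with open(path) as fh:
        raw = json.load(fh)
    return {int(k): ProjectiveTransform(np.asarray(m)) for k, m in raw.items()}
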