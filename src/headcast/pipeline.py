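"""Pipeline stages: each one a pure function of its on-disk inputs.

Stage outputs are plain-text artifacts (CSV / GeoJSON / JSON) with
self-describing headers; each stage reads only what upstream stages wrote
under the run directory, so chaining ``run_all`` equals running the stages
individually.  A missing upstream artifact raises
:class:`~headcast.errors.PipelineError` naming the command that produces it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import RunConfig
from .errors import PipelineError
from .field_geometry import (
    TilingConfig,
    assign_ids,
    detect_ridges,
    detections_to_positions,
    nms_merge,
)
from .growth_model import (
    GrowthModelParams,
    TemperatureSeries,
    anchor_drone_series,
    build_prediction_model,
    fit_init_model,
    predict_hd,
)
from .head_morphometry import agreement_metrics, min_area_rect_hd_batch
from .harvest_economics import optimal_harvest_date
from .synthetic_field import (
    build_sector_transforms,
    emit_polygons_and_detections,
    generate_layout,
    make_growth_truth,
    read_detections_csv,
    read_polygons_geojson,
    read_transforms_json,
    simulate_growth,
    synth_temperatures,
    write_detections_csv,
    write_polygons_geojson,
    write_transforms_json,
)

logger = logging.getLogger(__name__)


def _require(outdir: Path, name: str, producer: str) -> Path:
    path = Path(outdir) / name
    if not path.exists():
        raise PipelineError(
            f"missing upstream artifact {name!r}; run `headcast {producer}` first"
        )
    return path


def _tiling_and_origin(cfg: RunConfig):
    """Derive the virtual image extent covering the field at the configured GSD."""
    xmin, ymin, xmax, ymax = cfg.layout.bounds()
    width = int(np.ceil((xmax - xmin) / cfg.gsd_m)) + 1
    height = int(np.ceil((ymax - ymin) / cfg.gsd_m)) + 1
    tiling = TilingConfig((width, height), cfg.sector_size, cfg.buffer_px)
    return tiling, (xmin, ymax)  # image top-left is the field's NW corner


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig, outdir) -> None:
    """Write the synthetic dataset: truth, temperatures, observations,
    polygons, detections, transforms, field-measurement sample."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config_resolved.yaml")

    layout = generate_layout(cfg.layout, cfg.stage_seed("layout"))
    truth = make_growth_truth(layout, cfg.growth, cfg.stage_seed("truth"))
    temps = synth_temperatures(
        cfg.temperature.start,
        cfg.temperature.end,
        cfg.temperature.monthly_means,
        cfg.temperature.ar1_rho,
        cfg.temperature.daily_sd,
        cfg.stage_seed("temps"),
    )
    all_dates = sorted(set(cfg.flight_dates) | set(cfg.field_measure_dates))
    observations = simulate_growth(truth, cfg.growth, temps, all_dates, cfg.stage_seed("growth"))

    tiling, geo_origin = _tiling_and_origin(cfg)
    transforms = build_sector_transforms(tiling, cfg.gsd_m, geo_origin)
    flight_obs = observations[observations["date"].isin(cfg.flight_dates)]
    polygons, detections = emit_polygons_and_detections(
        flight_obs,
        truth,
        tiling,
        transforms,
        cfg.stage_seed("emit"),
        n_vertices=cfg.n_vertices,
        vertex_noise_frac=cfg.vertex_noise_frac,
        seedling_box_m=cfg.seedling_box_m,
    )
    rng = np.random.default_rng(cfg.stage_seed("fieldsample"))
    n_sample = min(cfg.n_field_plants, len(truth))
    sample_ids = np.sort(rng.choice(truth["plant_id"].to_numpy(), n_sample, replace=False))

    truth.to_csv(outdir / "truth.csv", index=False)
    temps.to_frame().to_csv(outdir / "temperatures.csv", index=False)
    observations.to_csv(outdir / "observations.csv", index=False)
    write_polygons_geojson(polygons, outdir / "polygons.geojson")
    write_detections_csv(detections, outdir / "detections.csv")
    write_transforms_json(transforms, outdir / "transforms.json")
    pd.DataFrame({"plant_id": sample_ids}).to_csv(outdir / "field_sample.csv", index=False)
    logger.info(
        "simulate: %d plants, %d observations, %d polygons, %d detections",
        len(truth), len(observations), len(polygons), len(detections),
    )


def stage_positions(cfg: RunConfig, outdir) -> pd.DataFrame:
    """NMS-merge detections, map centres to geographic positions, detect
    ridges, assign plant IDs."""
    outdir = Path(outdir)
    detections = read_detections_csv(_require(outdir, "detections.csv", "simulate"))
    transforms = read_transforms_json(_require(outdir, "transforms.json", "simulate"))

    merged = nms_merge(detections, cfg.nms_iou)
    positions = detections_to_positions(merged, transforms)
    ridges = detect_ridges(positions, cfg.layout.ridge_spacing)
    ids = assign_ids(positions, ridges)
    frame = pd.DataFrame(
        {
            "plant_id": ids,
            "ridge": ridges,
            "x": positions[:, 0],
            "y": positions[:, 1],
            # ground-truth identity carried through for validation only
            "truth_plant_id": [d.plant_id for d in merged],
        }
    ).sort_values("plant_id")
    frame.to_csv(outdir / "positions.csv", index=False)
    _write_positions_geojson(frame, outdir / "positions.geojson")
    logger.info(
        "positions: %d detections -> %d merged (%d suppressed), %d ridges",
        len(detections), len(merged), len(detections) - len(merged), ridges.max() + 1,
    )
    return frame


def _write_positions_geojson(frame: pd.DataFrame, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(r.x), float(r.y)]},
            "properties": {"plant_id": int(r.plant_id), "ridge": int(r.ridge)},
        }
        for r in frame.itertuples()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def stage_measure(cfg: RunConfig, outdir) -> pd.DataFrame:
    """Polygon morphometry -> per-plant per-date head-diameter tables.

    Drone HDs (mm) come from the minimum-area-rectangle diameter of each
    head polygon, assigned to the nearest pipeline plant position; the field
    table restricts the simulated manual measurements to the sampled plants.
    Also writes per-date drone-vs-field agreement metrics where dates
    overlap.
    """
    outdir = Path(outdir)
    polygons = read_polygons_geojson(_require(outdir, "polygons.geojson", "simulate"))
    positions = pd.read_csv(_require(outdir, "positions.csv", "positions"))
    observations = pd.read_csv(_require(outdir, "observations.csv", "simulate"))
    sample = pd.read_csv(_require(outdir, "field_sample.csv", "simulate"))

    tree = cKDTree(positions[["x", "y"]].to_numpy())
    hd_mm = min_area_rect_hd_batch(polygons) * 1000.0  # metres -> mm
    centroids = np.array([p.vertices.mean(axis=0) for p in polygons]).reshape(-1, 2)
    _, idx = tree.query(centroids)
    hd_drone = pd.DataFrame(
        {
            "plant_id": positions["plant_id"].to_numpy()[idx],
            "date": [p.date for p in polygons],
            "hd_mm": hd_mm,
            "source": "drone",
        }
    )
    hd_drone.to_csv(outdir / "hd_drone.csv", index=False)

    field_obs = observations[
        observations["plant_id"].isin(sample["plant_id"])
        & observations["date"].isin(cfg.field_measure_dates)
    ]
    hd_field = field_obs.rename(columns={"field_hd_mm": "hd_mm"})[
        ["plant_id", "date", "hd_mm"]
    ].assign(source="field")
    hd_field.to_csv(outdir / "hd_field.csv", index=False)

    _write_agreement(outdir, cfg, hd_drone, positions, observations)
    logger.info("measure: %d drone HDs, %d field HDs", len(hd_drone), len(hd_field))
    return hd_drone


def _write_agreement(outdir, cfg, hd_drone, positions, observations) -> None:
    """Per-date r2 / RMSE between drone HDs and simulated field HDs."""
    id_map = positions.set_index("plant_id")["truth_plant_id"]
    drone = hd_drone.copy()
    drone["truth_plant_id"] = drone["plant_id"].map(id_map)
    merged = drone.merge(
        observations[["plant_id", "date", "field_hd_mm"]],
        left_on=["truth_plant_id", "date"],
        right_on=["plant_id", "date"],
        suffixes=("", "_truth"),
    )
    rows = []
    for date, grp in merged.groupby("date"):
        if len(grp) < 3:
            continue
        r2, rmse = agreement_metrics(grp["hd_mm"].to_numpy(), grp["field_hd_mm"].to_numpy())
        rows.append({"date": date, "n": len(grp), "r2": r2, "rmse_mm": rmse})
    pd.DataFrame(rows, columns=["date", "n", "r2", "rmse_mm"]).to_csv(
        outdir / "agreement.csv", index=False
    )


def stage_fit(cfg: RunConfig, outdir) -> dict:
    """Fit the initialization model on field data, anchor the drone series,
    fit the pooled prediction model."""
    outdir = Path(outdir)
    hd_field = pd.read_csv(_require(outdir, "hd_field.csv", "measure"))
    hd_drone = pd.read_csv(_require(outdir, "hd_drone.csv", "measure"))
    temps = TemperatureSeries.from_csv(_require(outdir, "temperatures.csv", "simulate"))

    init_params, init_info = fit_init_model(hd_field, temps, cfg.startup_band_mm)
    anchored = anchor_drone_series(hd_drone, init_params, temps)
    pred_params = build_prediction_model(anchored)

    with open(outdir / "model_init.json", "w") as fh:
        json.dump({**init_params.to_dict(), **init_info}, fh, indent=2)
    with open(outdir / "model_prediction.json", "w") as fh:
        json.dump(
            {
                **pred_params.to_dict(),
                "n_plants_anchored": len(anchored.t0),
                "n_plants_excluded": len(anchored.excluded),
            },
            fh,
            indent=2,
        )
    anchored_out = anchored.data.copy()
    anchored_out["date"] = anchored_out["date"].dt.strftime("%Y-%m-%d")
    anchored_out.to_csv(outdir / "anchored.csv", index=False)
    anchored.excluded.to_csv(outdir / "anchoring_exclusions.csv", index=False)
    logger.info(
        "fit: init (a=%.3f b=%.3f c=%.5f, %d plants, %d excluded); "
        "prediction (a=%.3f b=%.3f c=%.5f, %d pairs, %d plants excluded)",
        init_params.a, init_params.b, init_params.c,
        init_info["n_plants_used"], init_info["n_plants_excluded"],
        pred_params.a, pred_params.b, pred_params.c,
        len(anchored), len(anchored.excluded),
    )
    return {"init": init_params, "prediction": pred_params}


def stage_predict(cfg: RunConfig, outdir) -> pd.DataFrame:
    """Forward-predict every plant's HD for each candidate harvest date."""
    outdir = Path(outdir)
    with open(_require(outdir, "model_prediction.json", "fit")) as fh:
        pred_params = GrowthModelParams.from_dict(json.load(fh))
    anchored = pd.read_csv(_require(outdir, "anchored.csv", "fit"), parse_dates=["date"])
    temps = TemperatureSeries.from_csv(_require(outdir, "temperatures.csv", "simulate"))

    first = anchored.sort_values("date").groupby("plant_id").first()
    candidates = pd.date_range(cfg.harvest_start, cfg.harvest_end, freq="D")
    rows = []
    for plant_id, row in first.iterrows():
        t_first, date_first = float(row["t_sum"]), row["date"]
        for date in candidates:
            if date >= date_first:
                t = t_first + temps.clipped_sum(date_first, date)
            else:
                t = t_first - temps.clipped_sum(date, date_first)
            rows.append(
                {
                    "plant_id": plant_id,
                    "date": date.strftime("%Y-%m-%d"),
                    "hd_pred_mm": predict_hd(pred_params, t),
                }
            )
    predictions = pd.DataFrame(rows)
    predictions.to_csv(outdir / "predictions.csv", index=False)
    logger.info("predict: %d plants x %d dates", len(first), len(candidates))
    return predictions


def stage_optimize(cfg: RunConfig, outdir):
    """Grade the predicted cohort per date and select the optimal harvest
    date under each price case."""
    outdir = Path(outdir)
    predictions = pd.read_csv(_require(outdir, "predictions.csv", "predict"))
    per_date = {
        date: grp["hd_pred_mm"].to_numpy() / 10.0  # mm -> cm at the schema boundary
        for date, grp in predictions.groupby("date")
    }
    report = optimal_harvest_date(per_date, cfg.grade_cases)

    per_date_out = report.per_date.copy()
    per_date_out["date"] = per_date_out["date"].dt.strftime("%Y-%m-%d")
    per_date_out.to_csv(outdir / "harvest_report.csv", index=False)
    summary = {
        "optimal_date": {k: v.strftime("%Y-%m-%d") for k, v in report.optimal.items()},
        "deviation_loss": report.deviation_loss.to_dict(orient="records"),
    }
    with open(outdir / "harvest_report.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info("optimize: optimal date per case %s", summary["optimal_date"])
    return report


_STAGES = ("simulate", "positions", "measure", "fit", "predict", "optimize")


def run_all(cfg: RunConfig, outdir) -> None:
    """Run every stage in order on one run directory."""
    stage_simulate(cfg, outdir)
    stage_positions(cfg, outdir)
    stage_measure(cfg, outdir)
    stage_fit(cfg, outdir)
    stage_predict(cfg, outdir)
    stage_optimize(cfg, outdir)
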