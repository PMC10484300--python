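"""Cross-season swap validation: one season's model predicts the other.

Simulates a second, 2021-style season (warmer spring, split transplanting 8
days apart between the west and east halves, its own growth parameters),
runs the pipeline on it, then predicts its drone-measured head diameters
with the first season's prediction model.  Early-window correlations stay
high; once growth saturates the correlation degrades — the reason a
previous year's model is only a stand-in until current-year flights exist.
"""

import argparse
import json
import logging
import shutil
from pathlib import Path

import pandas as pd

from headcast.config import RunConfig, TemperatureConfig
from headcast.growth_model import GrowthModelParams, TemperatureSeries, swap_validate
from headcast.pipeline import run_all
from headcast.synthetic_field import MONTHLY_MEANS_2021, GrowthTruthConfig


def season2021_config(seed: int) -> RunConfig:
    return RunConfig(
        seed=seed,
        growth=GrowthTruthConfig(
            a=5.57, b=2.11, c=0.00558, season_start="2021-05-07", east_shift_days=8
        ),
        temperature=TemperatureConfig(
            start="2021-03-01", end="2021-06-15", monthly_means=dict(MONTHLY_MEANS_2021)
        ),
        flight_dates=("2021-05-12", "2021-05-14", "2021-05-15", "2021-05-19",
                      "2021-05-20", "2021-05-26"),
        field_measure_dates=tuple(f"2021-05-{d:02d}" for d in range(4, 27, 2)),
        harvest_start="2021-05-12",
        harvest_end="2021-05-26",
    )


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--raw", type=Path, default=Path("scratch/analysis"),
                        help="Directory for bulky run artifacts.")
    parser.add_argument("--out", type=Path, default=Path("results/analysis"),
                        help="Directory for summary tables.")
    args = parser.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(message)s")

    dir_2020 = args.raw / "season2020"
    model_2020_path = dir_2020 / "model_prediction.json"
    if not model_2020_path.exists():
        raise SystemExit("run scripts 01-05 first: season2020 prediction model missing")
    model_2020 = GrowthModelParams.from_dict(json.loads(model_2020_path.read_text()))

    dir_2021 = args.raw / "season2021"
    cfg = season2021_config(args.seed + 1)
    run_all(cfg, dir_2021)
    init_2021 = GrowthModelParams.from_dict(
        json.loads((dir_2021 / "model_init.json").read_text())
    )
    hd_2021 = pd.read_csv(dir_2021 / "hd_drone.csv")
    temps_2021 = TemperatureSeries.from_csv(dir_2021 / "temperatures.csv")

    result = swap_validate(model_2020, hd_2021, init_2021, temps_2021)
    args.out.mkdir(parents=True, exist_ok=True)
    result.to_csv(args.out / "swap_validation.csv", index=False)
    for name in ("harvest_report.csv", "harvest_report.json"):
        shutil.copy2(dir_2021 / name, args.out / f"season2021_{name}")
    report = json.loads((dir_2021 / "harvest_report.json").read_text())
    print("season-2020 model predicting season-2021 drone HDs:")
    for row in result.itertuples():
        print(f"  {row.date.date()}: n={row.n}  r2={row.r2:.3f}  RMSE={row.rmse_mm:.2f} mm  "
              f"median pred/meas {row.pred_q50 / 10:.1f}/{row.meas_q50 / 10:.1f} cm")
    print(f"season-2021 optimal harvest dates: {report['optimal_date']}")


if __name__ == "__main__":
    main()
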