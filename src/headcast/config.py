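"""Run configuration: one structured file drives every stage.

Every quantity a stage needs — layout, growth truth, temperature synthesis,
flight and field-measurement calendars, tiling, NMS threshold, grade/price
cases, model-fit options, the harvest candidate window, and the root seed —
lives in a single :class:`RunConfig`, serialisable to YAML.  Two runs with
identical resolved configs produce identical outputs: all randomness flows
from the root seed, split per stage by spawning one child seed sequence per
stage name, in the fixed order: layout, truth, temps, growth, emit,
fieldsample.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .errors import InvalidConfigError
from .harvest_economics import GradeClass, GradeSchema, default_schemas
from .synthetic_field import FieldLayout, GrowthTruthConfig, MONTHLY_MEANS_2020

_STAGE_NAMES = ("layout", "truth", "temps", "growth", "emit", "fieldsample")


@dataclass(frozen=True)
class TemperatureConfig:
    start: str = "2020-03-01"
    end: str = "2020-06-15"
    monthly_means: dict = field(default_factory=lambda: dict(MONTHLY_MEANS_2020))
    ar1_rho: float = 0.7
    daily_sd: float = 2.0


@dataclass
class RunConfig:
    seed: int = 7
    layout: FieldLayout = field(default_factory=FieldLayout)
    growth: GrowthTruthConfig = field(
        default_factory=lambda: GrowthTruthConfig(season_start="2020-05-11")
    )
    temperature: TemperatureConfig = field(default_factory=TemperatureConfig)
    flight_dates: tuple[str, ...] = (
        "2020-05-18",
        "2020-05-20",
        "2020-05-22",
        "2020-05-25",
        "2020-05-26",
        "2020-05-28",
    )
    field_measure_dates: tuple[str, ...] = tuple(
        f"2020-05-{d:02d}" for d in range(8, 29, 2)
    )
    n_field_plants: int = 120
    sector_size: int = 1300
    buffer_px: int = 200
    gsd_m: float = 0.004
    nms_iou: float = 0.5
    n_vertices: int = 64
    vertex_noise_frac: float = 0.02
    seedling_box_m: float = 0.20
    startup_band_mm: tuple[float, float] = (30.0, 35.0)
    harvest_start: str = "2020-05-18"
    harvest_end: str = "2020-05-28"
    grade_cases: list[GradeSchema] = field(default_factory=default_schemas)

    def __post_init__(self):
        n = (self.layout.n_ridges or 0) * (self.layout.plants_per_ridge or 0)
        if self.layout.n_ridges is not None and n == 0:
            raise InvalidConfigError("layout admits zero plants")
        if not (0.0 < self.nms_iou < 1.0):
            raise InvalidConfigError("nms_iou must lie strictly in (0, 1)")
        if len(self.flight_dates) < 2:
            raise InvalidConfigError("need at least 2 flight dates")

    # -- seeds -------------------------------------------------------------
    def stage_seed(self, stage: str) -> int:
        """Per-stage 31-bit seed derived from the root seed.

        The root seed spawns one child ``SeedSequence`` per stage name in a
        fixed order, so stages are independent and the whole run is
        reproducible from the single root.
        """
        if stage not in _STAGE_NAMES:
            raise InvalidConfigError(f"unknown stage {stage!r}; known: {_STAGE_NAMES}")
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGE_NAMES))
        child = children[_STAGE_NAMES.index(stage)]
        return int(child.generate_state(1)[0] % (2**31))

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["layout"] = asdict(self.layout)
        d["layout"]["origin"] = list(self.layout.origin)
        if self.layout.field_bounds is not None:
            d["layout"]["field_bounds"] = list(self.layout.field_bounds)
        d["growth"] = asdict(self.growth)
        d["temperature"] = asdict(self.temperature)
        d["flight_dates"] = list(self.flight_dates)
        d["field_measure_dates"] = list(self.field_measure_dates)
        d["startup_band_mm"] = list(self.startup_band_mm)
        d["grade_cases"] = [
            {
                "case_label": s.case_label,
                "sellable_min_cm": s.sellable_min_cm,
                "sellable_max_cm": s.sellable_max_cm,
                "classes": [
                    {"label": g.label, "lower_cm": g.lower_cm, "upper_cm": g.upper_cm,
                     "price": g.price}
                    for g in s.classes
                ],
            }
            for s in self.grade_cases
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "layout" in d:
            d["layout"] = FieldLayout(**{**d["layout"],
                                         "origin": tuple(d["layout"].get("origin", (0.0, 0.0)))})
        if "growth" in d:
            d["growth"] = GrowthTruthConfig(**d["growth"])
        if "temperature" in d:
            tc = dict(d["temperature"])
            if "monthly_means" in tc:
                tc["monthly_means"] = {int(k): float(v) for k, v in tc["monthly_means"].items()}
            d["temperature"] = TemperatureConfig(**tc)
        for key in ("flight_dates", "field_measure_dates"):
            if key in d:
                d[key] = tuple(d[key])
        if "startup_band_mm" in d:
            d["startup_band_mm"] = tuple(d["startup_band_mm"])
        if "grade_cases" in d:
            d["grade_cases"] = [
                GradeSchema(
                    classes=tuple(GradeClass(**g) for g in s["classes"]),
                    sellable_min_cm=s.get("sellable_min_cm", 11.0),
                    sellable_max_cm=s.get("sellable_max_cm", 14.0),
                    case_label=s.get("case_label", "default"),
                )
                for s in d["grade_cases"]
            ]
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
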