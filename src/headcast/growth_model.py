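"""Thermal-time growth model for broccoli head diameter.

The head diameter HD (in millimetres) of an individual is modelled as a
Gompertz-type curve in accumulated effective temperature ("temperature sum")
T::

    ln HD = a - b * exp(-c * T)

where T is the sum of daily mean air temperatures, each day clipped to the
effective range [0, 20] degC, and (a, b, c) are field-specific parameters:
``exp(a)`` is the asymptotic head diameter, ``exp(a - b)`` the head diameter
at T = 0 (the startup size at which a head first becomes measurable, around
3-3.5 cm), and ``c`` the rate per degC-day.

The modelling protocol has two regressions.  An *initialization* model is fit
to manual field measurements whose thermal-time axis is anchored at the
startup size.  That model is then inverted at each plant's first drone-derived
head diameter to place the plant on the T axis (its ``T0``); later flights add
clipped temperature-sum increments.  The pooled anchored pairs are refit to
give the *prediction* model used for forward harvest-window prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    DomainError,
    FitError,
    InvalidDataError,
    MissingDataError,
    UndefinedMetricError,
)

logger = logging.getLogger(__name__)

#: Effective-temperature clipping limits (degC) for daily means.
CLIP_LOWER_C = 0.0
CLIP_UPPER_C = 20.0


class TemperatureSeries:
    """Daily mean temperatures on a gap-free, strictly increasing date index.

    Parameters
    ----------
    dates :
        Sequence of dates (anything ``pandas.to_datetime`` accepts).
    tmean_c :
        Daily mean temperatures in degC, one per date.
    """

    def __init__(self, dates, tmean_c):
        idx = pd.DatetimeIndex(pd.to_datetime(list(dates))).normalize()
        values = np.asarray(tmean_c, dtype=float)
        if len(idx) != len(values):
            raise InvalidDataError("dates and temperatures differ in length")
        if len(idx) == 0:
            raise InvalidDataError("temperature series is empty")
        diffs = np.diff(idx.asi8)
        one_day = 86_400_000_000_000
        if len(diffs) and not np.all(diffs == one_day):
            raise InvalidDataError(
                "temperature series must be daily, strictly increasing, gap-free"
            )
        self._series = pd.Series(values, index=idx, name="tmean_c")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TemperatureSeries":
        """Build from a DataFrame with ``date`` and ``tmean_C`` columns."""
        return cls(frame["date"], frame["tmean_C"])

    @classmethod
    def from_csv(cls, path) -> "TemperatureSeries":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self._series.index.strftime("%Y-%m-%d"), "tmean_C": self._series.values}
        )

    # -- queries -----------------------------------------------------------
    @property
    def start(self) -> pd.Timestamp:
        return self._series.index[0]

    @property
    def end(self) -> pd.Timestamp:
        return self._series.index[-1]

    def __len__(self) -> int:
        return len(self._series)

    def covers(self, date) -> bool:
        d = pd.Timestamp(date).normalize()
        return self.start <= d <= self.end

    def clipped_sum(self, start, end) -> float:
        """Clipped temperature sum over the half-open window ``(start, end]``.

        Each daily mean is clipped to [0, 20] degC before summation, so the
        result is additive over adjacent windows and bounded by 20 x (number
        of days).  ``start == end`` gives 0.
        """
        s = pd.Timestamp(start).normalize()
        e = pd.Timestamp(end).normalize()
        if e < s:
            raise MissingDataError(f"window end {e.date()} precedes start {s.date()}")
        if s == e:
            return 0.0
        if s + pd.Timedelta(days=1) < self.start or e > self.end:
            raise MissingDataError(
                f"window ({s.date()}, {e.date()}] not covered by series "
                f"[{self.start.date()}, {self.end.date()}]"
            )
        window = self._series.loc[s + pd.Timedelta(days=1): e]
        if len(window) != (e - s).days:
            raise MissingDataError("temperature series has gaps inside the window")
        return float(np.clip(window.values, CLIP_LOWER_C, CLIP_UPPER_C).sum())


@dataclass(frozen=True)
class GrowthModelParams:
    """Parameters (a, b, c) of ``ln HD = a - b * exp(-c * T)`` with HD in mm."""

    a: float
    b: float
    c: float
    residual_sd: float | None = None
    n_obs: int | None = None

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise InvalidDataError(f"growth parameters must be positive, got {self}")

    @property
    def startup_hd_mm(self) -> float:
        """Head diameter at T = 0, ``exp(a - b)``."""
        return float(np.exp(self.a - self.b))

    @property
    def asymptote_hd_mm(self) -> float:
        return float(np.exp(self.a))

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "residual_sd": self.residual_sd,
            "n_obs": self.n_obs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthModelParams":
        return cls(**{k: d.get(k) for k in ("a", "b", "c", "residual_sd", "n_obs")})


def predict_hd(params: GrowthModelParams, t_sum):
    """Head diameter (mm) at temperature sum ``t_sum`` (degC-day).

    Strictly increasing in T, bounded above by ``exp(a)``; T may be any real
    (negative values describe heads below the startup size).
    """
    t = np.asarray(t_sum, dtype=float)
    hd = np.exp(params.a - params.b * np.exp(-params.c * t))
    return float(hd) if np.isscalar(t_sum) or t.ndim == 0 else hd


def invert_model(params: GrowthModelParams, hd_mm):
    """Temperature sum at which the curve reaches ``hd_mm``.

    Closed form ``T = -(1/c) * ln((a - ln HD) / b)``; defined for
    ``0 < ln HD < a``.  Values below the startup size give negative T.

    Raises
    ------
    DomainError
        If ``hd_mm <= 0`` or ``ln hd_mm >= a`` (at or beyond the asymptote).
    """
    hd = np.asarray(hd_mm, dtype=float)
    if np.any(hd <= 0):
        raise DomainError("head diameter must be positive")
    ln_hd = np.log(hd)
    if np.any(ln_hd >= params.a):
        raise DomainError(
            f"head diameter at or beyond the asymptote exp(a) = {params.asymptote_hd_mm:.1f} mm"
        )
    t = -np.log((params.a - ln_hd) / params.b) / params.c
    return float(t) if np.isscalar(hd_mm) or hd.ndim == 0 else t


def fit_growth_model(t_sum, hd_mm) -> GrowthModelParams:
    """Fit (a, b, c) by nonlinear least squares on the ln-scale residual.

    Minimizes ``sum (ln HD_i - (a - b exp(-c T_i)))^2``.  Initial guess:
    ``a0 = max(ln HD) + 0.3``, ``b0 = a0 - min(ln HD)``, ``c0 = 0.005``.

    Parameters
    ----------
    t_sum, hd_mm :
        Paired temperature sums (degC-day) and head diameters (mm); at least
        4 points spanning a nondegenerate T range.

    Raises
    ------
    InvalidDataError
        If any HD is non-positive.
    FitError
        If the problem is under-determined or the optimizer fails; carries
        optimizer diagnostics.
    """
    t = np.asarray(t_sum, dtype=float)
    hd = np.asarray(hd_mm, dtype=float)
    if t.shape != hd.shape or t.ndim != 1:
        raise InvalidDataError("t_sum and hd_mm must be 1-d arrays of equal length")
    if np.any(hd <= 0):
        raise InvalidDataError("head diameters must be positive for the ln-scale fit")
    if len(t) < 4:
        raise FitError(f"under-determined fit: {len(t)} points < 4")
    if np.ptp(t) <= 0:
        raise FitError("degenerate temperature-sum range (all T equal)")

    ln_hd = np.log(hd)
    a0 = float(ln_hd.max()) + 0.3
    b0 = a0 - float(ln_hd.min())
    x0 = np.array([a0, b0, 0.005])

    def resid(x):
        a, b, c = x
        return ln_hd - (a - b * np.exp(-c * t))

    result = least_squares(
        resid,
        x0,
        bounds=([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=10_000,
    )
    if not result.success:
        raise FitError(
            f"growth-model fit did not converge: {result.message}",
            diagnostics={"status": result.status, "cost": result.cost, "nfev": result.nfev},
        )
    a, b, c = result.x
    dof = len(t) - 3
    residual_sd = float(np.sqrt(2 * result.cost / dof)) if dof > 0 else float("nan")
    return GrowthModelParams(a=a, b=b, c=c, residual_sd=residual_sd, n_obs=len(t))


@dataclass
class AnchoredSeries:
    """Per-plant (T_i, HD_i) pairs anchored on the thermal-time axis.

    ``data`` holds one row per plant x flight with columns ``plant_id``,
    ``date``, ``t_sum``, ``hd_mm``; ``t0`` maps plant to its inversion-derived
    starting temperature sum; ``excluded`` records plants whose first-flight
    diameter fell outside the inversion domain, with the reason.
    """

    data: pd.DataFrame
    t0: dict = field(default_factory=dict)
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["plant_id", "reason"])
    )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        return self.data["t_sum"].to_numpy(), self.data["hd_mm"].to_numpy()


def anchor_drone_series(
    hd_table: pd.DataFrame,
    init_params: GrowthModelParams,
    temps: TemperatureSeries,
    flight_dates=None,
) -> AnchoredSeries:
    """Anchor drone-measured head diameters on the thermal-time axis.

    For each plant, ``T0 = invert_model(init_params, first-flight HD)``; each
    later flight ``i`` gets ``T_i = T0 + clipped_sum(first date, date_i)``.
    Plants whose first-flight HD lies outside the inversion domain are
    excluded with a logged reason.

    Parameters
    ----------
    hd_table :
        Columns ``plant_id``, ``date``, ``hd_mm``; one row per plant x flight.
    flight_dates :
        Optional subset of dates to use; defaults to all dates present.
    """
    table = hd_table.copy()
    table["date"] = pd.to_datetime(table["date"]).dt.normalize()
    if flight_dates is not None:
        keep = pd.DatetimeIndex(pd.to_datetime(list(flight_dates))).normalize()
        table = table[table["date"].isin(keep)]
    if table.empty:
        raise InvalidDataError("no head-diameter observations to anchor")

    rows, t0_map, excluded = [], {}, []
    for plant_id, grp in table.sort_values("date").groupby("plant_id", sort=True):
        first = grp.iloc[0]
        try:
            t0 = invert_model(init_params, float(first["hd_mm"]))
        except DomainError as exc:
            logger.warning("plant %s excluded from anchoring: %s", plant_id, exc)
            excluded.append({"plant_id": plant_id, "reason": str(exc)})
            continue
        t0_map[plant_id] = t0
        for _, obs in grp.iterrows():
            t_i = t0 + temps.clipped_sum(first["date"], obs["date"])
            rows.append(
                {
                    "plant_id": plant_id,
                    "date": obs["date"],
                    "t_sum": t_i,
                    "hd_mm": float(obs["hd_mm"]),
                }
            )
    data = pd.DataFrame(rows, columns=["plant_id", "date", "t_sum", "hd_mm"])
    return AnchoredSeries(
        data=data, t0=t0_map, excluded=pd.DataFrame(excluded, columns=["plant_id", "reason"])
    )


def build_prediction_model(anchored: AnchoredSeries) -> GrowthModelParams:
    """Pooled growth-model fit over all anchored (T, HD) pairs.

    This is the model used for forward harvest-window prediction.
    """
    if len(anchored) == 0:
        raise InvalidDataError("anchored series is empty")
    t, hd = anchored.pairs
    return fit_growth_model(t, hd)


def fit_init_model(
    field_obs: pd.DataFrame,
    temps: TemperatureSeries,
    startup_band_mm: tuple[float, float] = (30.0, 35.0),
) -> tuple[GrowthModelParams, dict]:
    """Initialization model from manual field measurements.

    Each plant's T = 0 origin is the first date at which its measured HD lies
    inside ``startup_band_mm`` (the size at which a head first becomes
    measurable); observations from that date onward contribute pooled
    ``(clipped_sum(origin, date), HD)`` pairs.  Plants never entering the band
    are excluded.

    Returns the fitted parameters and an info dict with ``n_plants_used`` and
    ``n_plants_excluded``.
    """
    obs = field_obs.copy()
    obs["date"] = pd.to_datetime(obs["date"]).dt.normalize()
    lo, hi = startup_band_mm
    t_list, hd_list, used, skipped = [], [], 0, 0
    for _, grp in obs.sort_values("date").groupby("plant_id", sort=True):
        in_band = grp[(grp["hd_mm"] >= lo) & (grp["hd_mm"] <= hi)]
        if in_band.empty:
            skipped += 1
            continue
        origin = in_band.iloc[0]["date"]
        used += 1
        for _, row in grp[grp["date"] >= origin].iterrows():
            t_list.append(temps.clipped_sum(origin, row["date"]))
            hd_list.append(float(row["hd_mm"]))
    if used == 0:
        raise InvalidDataError("no plant entered the startup band; cannot initialize")
    params = fit_growth_model(np.array(t_list), np.array(hd_list))
    return params, {"n_plants_used": used, "n_plants_excluded": skipped}


def swap_validate(
    model_params: GrowthModelParams,
    hd_table: pd.DataFrame,
    init_params: GrowthModelParams,
    temps: TemperatureSeries,
) -> pd.DataFrame:
    """Cross-year validation: predict one year's drone HDs with another year's model.

    The target year's data are anchored with *their own* initialization model;
    the foreign prediction model is then evaluated at the anchored temperature
    sums and compared per flight date with the drone-measured diameters.

    Returns a per-date frame with ``n``, ``r2``, ``rmse_mm`` and summary
    quantiles (q10/q50/q90) of both distributions.
    """
    from .head_morphometry import agreement_metrics  # local import avoids a cycle

    anchored = anchor_drone_series(hd_table, init_params, temps)
    if len(anchored) == 0:
        raise InvalidDataError("nothing to validate: all plants excluded at anchoring")
    data = anchored.data.copy()
    data["hd_pred_mm"] = predict_hd(model_params, data["t_sum"].to_numpy())

    rows = []
    for date, grp in data.groupby("date", sort=True):
        if len(grp) < 3:
            raise UndefinedMetricError(f"fewer than 3 pairs on {date.date()}")
        r2, rmse = agreement_metrics(grp["hd_pred_mm"].to_numpy(), grp["hd_mm"].to_numpy())
        q_pred = np.quantile(grp["hd_pred_mm"], [0.1, 0.5, 0.9])
        q_meas = np.quantile(grp["hd_mm"], [0.1, 0.5, 0.9])
        rows.append(
            {
                "date": date,
                "n": len(grp),
                "r2": r2,
                "rmse_mm": rmse,
                "pred_q10": q_pred[0],
                "pred_q50": q_pred[1],
                "pred_q90": q_pred[2],
                "meas_q10": q_meas[0],
                "meas_q50": q_meas[1],
                "meas_q90": q_meas[2],
            }
        )
    return pd.DataFrame(rows)
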