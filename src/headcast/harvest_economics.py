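"""Grading, income simulation, and one-pass harvest-date selection.

Japanese-market broccoli is shipped in three size grades — M (11-12 cm),
L (12-13 cm), 2L (13 cm and up) — with heads outside the sellable envelope
(below 11 cm or above 14 cm) unsold ("grade-out", the on-farm food loss).
Grading every predicted head for each candidate harvest date gives a
per-date income; the optimal single-pass harvest date is the income argmax,
and the deviation-loss curve quantifies how quickly a one- or two-day miss
erodes income.

Class intervals are half-open ``[lower, upper)``; the sellable envelope is
checked first, so its inclusive upper bound (14 cm by default) caps the top
grade regardless of the grade table's printed upper limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidDataError

NONSTANDARD = "NONSTANDARD"


@dataclass(frozen=True)
class GradeClass:
    label: str
    lower_cm: float  # inclusive
    upper_cm: float  # exclusive
    price: float  # currency units per head

    def __post_init__(self):
        if not (0 < self.lower_cm < self.upper_cm):
            raise InvalidConfigError(f"bad interval for grade {self.label}")
        if self.price < 0:
            raise InvalidConfigError(f"negative price for grade {self.label}")


@dataclass(frozen=True)
class GradeSchema:
    """Ordered size classes, per-class unit prices, and the sellable envelope."""

    classes: tuple[GradeClass, ...]
    sellable_min_cm: float = 11.0
    sellable_max_cm: float = 14.0  # inclusive
    case_label: str = "default"

    def __post_init__(self):
        if not self.classes:
            raise InvalidConfigError("grade schema needs at least one class")
        ordered = sorted(self.classes, key=lambda g: g.lower_cm)
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.lower_cm < prev.upper_cm:
                raise InvalidConfigError(
                    f"overlapping grade intervals: {prev.label} and {nxt.label}"
                )
        object.__setattr__(self, "classes", tuple(ordered))
        if self.sellable_min_cm >= self.sellable_max_cm:
            raise InvalidConfigError("sellable envelope is empty")

    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.classes]

    def price_of(self, label: str) -> float:
        if label == NONSTANDARD:
            return 0.0
        for g in self.classes:
            if g.label == label:
                return g.price
        raise InvalidConfigError(f"unknown grade label {label!r}")


def default_schemas() -> list[GradeSchema]:
    """The two shipped price cases.

    The L price is fixed at $1.00; the M/2L prices are configurable
    stand-ins bracketing a large (case 1) and a small (case 2) between-grade
    price difference.  The 2L interval runs to 15 cm but the sellable
    envelope caps sales at 14 cm.
    """
    def schema(label, m, l, xl):  # noqa: E741 - grade names
        return GradeSchema(
            classes=(
                GradeClass("M", 11.0, 12.0, m),
                GradeClass("L", 12.0, 13.0, l),
                GradeClass("2L", 13.0, 15.0, xl),
            ),
            case_label=label,
        )

    return [schema("case1", 0.70, 1.00, 1.30), schema("case2", 0.95, 1.00, 1.05)]


def grade(hd_cm: float, schema: GradeSchema) -> str:
    """Grade label for one head diameter (cm), or NONSTANDARD.

    Heads outside the sellable envelope are NONSTANDARD even when a class
    interval would nominally cover them.
    """
    if hd_cm <= 0:
        raise InvalidDataError("head diameter must be positive")
    if hd_cm < schema.sellable_min_cm or hd_cm > schema.sellable_max_cm:
        return NONSTANDARD
    for g in schema.classes:
        if g.lower_cm <= hd_cm < g.upper_cm:
            return g.label
    for g in schema.classes:  # inclusive envelope top (e.g. 14.0 with a [13, 14) class)
        if g.lower_cm <= hd_cm <= g.upper_cm:
            return g.label
    return NONSTANDARD


def income_for_date(hds_cm, schema: GradeSchema) -> tuple[dict[str, int], float, float]:
    """Counts per grade, total income, and grade-out proportion for one date.

    Income is ``sum over grades of count x unit price``; NONSTANDARD heads
    contribute zero.  Vectorised over the full cohort.
    """
    hds = np.asarray(hds_cm, dtype=float)
    if hds.size == 0:
        raise InvalidDataError("empty head-diameter list")
    counts = {g.label: 0 for g in schema.classes}
    counts[NONSTANDARD] = 0
    sellable = (hds >= schema.sellable_min_cm) & (hds <= schema.sellable_max_cm)
    counts[NONSTANDARD] = int(np.sum(~sellable))
    income = 0.0
    matched = np.zeros(hds.shape, dtype=bool)
    for g in schema.classes:
        in_class = sellable & (hds >= g.lower_cm) & (hds < g.upper_cm) & ~matched
        # inclusive envelope top falls into the last class covering it
        in_class |= sellable & ~matched & (hds == schema.sellable_max_cm) & (
            (g.lower_cm <= schema.sellable_max_cm) & (schema.sellable_max_cm <= g.upper_cm)
        )
        matched |= in_class
        counts[g.label] = int(np.sum(in_class))
        income += counts[g.label] * g.price
    counts[NONSTANDARD] += int(np.sum(sellable & ~matched))
    return counts, float(income), counts[NONSTANDARD] / hds.size


@dataclass
class HarvestReport:
    """Per-date grading/income table and the optimal date per price case."""

    per_date: pd.DataFrame  # date, case, counts..., nonstandard_prop, income
    optimal: dict[str, pd.Timestamp]  # case label -> optimal date
    deviation_loss: pd.DataFrame  # case, offset_days, income, relative_income

    def income_curve(self, case_label: str) -> pd.Series:
        sub = self.per_date[self.per_date["case"] == case_label]
        return sub.set_index("date")["income"]


def optimal_harvest_date(
    per_date_hds_cm: dict,
    schemas: list[GradeSchema],
) -> HarvestReport:
    """Select the income-maximising one-pass harvest date per price case.

    ``per_date_hds_cm`` maps candidate harvest dates to cohort head
    diameters (cm).  Ties are broken by the earliest date (less senescence
    risk).  The report also carries the deviation-loss curve: income at each
    day offset from the optimum, relative to the optimal income.
    """
    if len(per_date_hds_cm) < 2:
        raise InvalidDataError("need at least 2 candidate harvest dates")
    dates = sorted(pd.Timestamp(d) for d in per_date_hds_cm)
    hds_by_date = {pd.Timestamp(d): np.asarray(v, dtype=float) for d, v in per_date_hds_cm.items()}

    rows, optimal = [], {}
    for schema in schemas:
        incomes = {}
        for date in dates:
            counts, income, prop = income_for_date(hds_by_date[date], schema)
            incomes[date] = income
            row = {"date": date, "case": schema.case_label, "income": income,
                   "nonstandard_prop": prop}
            row.update({f"n_{k}": v for k, v in counts.items()})
            rows.append(row)
        best_income = max(incomes.values())
        optimal[schema.case_label] = min(d for d, v in incomes.items() if v == best_income)

    per_date = pd.DataFrame(rows)
    dev_rows = []
    for schema in schemas:
        opt = optimal[schema.case_label]
        sub = per_date[per_date["case"] == schema.case_label]
        opt_income = float(sub.loc[sub["date"] == opt, "income"].iloc[0])
        for _, row in sub.iterrows():
            dev_rows.append(
                {
                    "case": schema.case_label,
                    "offset_days": int((row["date"] - opt).days),
                    "income": row["income"],
                    "relative_income": row["income"] / opt_income if opt_income > 0 else np.nan,
                }
            )
    return HarvestReport(
        per_date=per_date, optimal=optimal, deviation_loss=pd.DataFrame(dev_rows)
    )
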