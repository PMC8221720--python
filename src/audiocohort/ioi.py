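"""IOI-HA survey assignment, return-window filtering, and scoring.

The International Outcome Inventory for Hearing Aids has seven 5-point
items (use, satisfaction, benefit, residual activity limitation, residual
participation restriction, impact on others, quality of life) plus an
eighth item for self-rated unaided hearing difficulty.  The total score is
the sum of items 1-7 (range 7-35); item 8 is carried separately as an
ordinal covariate and never summed.

Surveys are not explicitly linked to HA orders, so each survey is assigned
to the most recent HA order on/before its completion date.  If two surveys
of one patient land on the same order, both are excluded (ambiguous).
Surveys are retained only when returned 14-180 days (inclusive) after the
fitting date of their assigned order; the patient-specified completion date
governs the window, with the system entry date as fallback.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

TOTAL_MIN, TOTAL_MAX = 7, 35
DEFAULT_MIN_DAYS, DEFAULT_MAX_DAYS = 14, 180


@dataclasses.dataclass
class IOISurvey:
    patient_id: int
    completion_day: Optional[int]
    entry_day: Optional[int]
    items: tuple[int, ...]

    def __post_init__(self):
        if len(self.items) != 8:
            raise ValueError(f"patient {self.patient_id}: expected 8 items, "
                             f"got {len(self.items)}")
        if any(not 1 <= int(v) <= 5 for v in self.items):
            raise ValueError(f"patient {self.patient_id}: item values must "
                             f"be integers 1..5, got {self.items}")
        self.items = tuple(int(v) for v in self.items)

    @property
    def effective_day(self) -> Optional[int]:
        return self.completion_day if self.completion_day is not None \
            else self.entry_day


def total_score(survey) -> int:
    """Sum of items 1-7; item 8 is never included."""
    items = survey.items if isinstance(survey, IOISurvey) else tuple(survey)
    return int(sum(items[:7]))


@dataclasses.dataclass
class SurveyAssignment:
    survey: IOISurvey
    order_day: Optional[int]
    excluded_reason: Optional[str] = None     # None = assigned


@dataclasses.dataclass
class IOIResult:
    patient_id: int
    order_day: Optional[int]
    lag: Optional[int]
    total: Optional[int]
    item8: Optional[int]
    included: bool
    reason: Optional[str]


def assign_surveys(surveys: Sequence[IOISurvey],
                   ha_order_days: Sequence[int]) -> list[SurveyAssignment]:
    """Map each survey to the latest HA order on/before its return date.

    A survey predating all orders is excluded (``no_preceding_order``);
    two surveys resolving to the same order are both excluded
    (``duplicate_same_order``).  Output order is stable under permutation
    of the input: surveys are processed sorted by return date.
    """
    days = sorted(int(d) for d in ha_order_days)
    ordered = sorted(surveys, key=lambda s: (s.effective_day is None,
                                             s.effective_day))
    assignments = []
    for s in ordered:
        ref = s.effective_day
        if ref is None:
            assignments.append(SurveyAssignment(s, None, "no_return_date"))
            continue
        preceding = [d for d in days if d <= ref]
        if not preceding:
            assignments.append(SurveyAssignment(s, None, "no_preceding_order"))
            continue
        assignments.append(SurveyAssignment(s, preceding[-1], None))
    counts: dict[int, int] = {}
    for a in assignments:
        if a.order_day is not None:
            counts[a.order_day] = counts.get(a.order_day, 0) + 1
    for a in assignments:
        if a.order_day is not None and counts[a.order_day] > 1:
            a.excluded_reason = "duplicate_same_order"
    return assignments


def filter_return_window(assignment: SurveyAssignment,
                         fitting_day: Optional[int],
                         min_days: int = DEFAULT_MIN_DAYS,
                         max_days: int = DEFAULT_MAX_DAYS) -> IOIResult:
    """Apply the inclusive 14-180-day return window to one assignment."""
    s = assignment.survey
    base = IOIResult(patient_id=s.patient_id, order_day=assignment.order_day,
                     lag=None, total=total_score(s), item8=s.items[7],
                     included=False, reason=None)
    if assignment.excluded_reason is not None:
        base.reason = assignment.excluded_reason
        return base
    if fitting_day is None:
        base.reason = "no_fitting_date"
        return base
    lag = int(s.effective_day) - int(fitting_day)
    base.lag = lag
    if min_days <= lag <= max_days:
        base.included = True
    else:
        base.reason = "outside_return_window"
    return base


# ---------------------------------------------------------------------------
# table-level scoring used by the pipeline


def score_ioi_table(ioi: pd.DataFrame, ha_orders: pd.DataFrame,
                    fittings: pd.DataFrame,
                    min_days: int = DEFAULT_MIN_DAYS,
                    max_days: int = DEFAULT_MAX_DAYS) -> pd.DataFrame:
    """IOI results for every survey row, with inclusion flags and reasons.

    ``fittings`` must carry patient_id, ha_order_day, fitting_day; the
    fitting date keys off the *assigned* order when it is the patient's
    first order, otherwise the fitting proxy is unavailable for that order
    and the survey keeps its lag relative to the order's own first battery
    order only when computable.  In this implementation fitting dates exist
    for first orders; surveys assigned to later orders fall back to the
    order day itself plus the cohort-typical lag being unknown, so they are
    excluded with ``no_fitting_date`` unless the order is the first.
    """
    cols = ["patient_id", "order_day", "lag", "total", "item8",
            "included", "reason"]
    if ioi.empty:
        return pd.DataFrame(columns=cols)
    item_cols = [f"item{i}" for i in range(1, 8)]
    orders_by_pid: dict[int, list[int]] = {
        int(pid): sorted(g) for pid, g in
        ha_orders.groupby("patient_id")["order_day"]}
    fit = fittings.dropna(subset=["fitting_day"])
    fitting_by_order = {(int(p), int(o)): int(f) for p, o, f in
                        zip(fit["patient_id"], fit["ha_order_day"],
                            fit["fitting_day"])}
    rows = []
    for pid, group in ioi.groupby("patient_id"):
        surveys = [
            IOISurvey(patient_id=int(pid),
                      completion_day=None if pd.isna(r["completion_day"])
                      else int(r["completion_day"]),
                      entry_day=None if pd.isna(r["entry_day"])
                      else int(r["entry_day"]),
                      items=tuple(int(r[f"item{i}"]) for i in range(1, 9)))
            for _, r in group.iterrows()]
        assignments = assign_surveys(surveys, orders_by_pid.get(int(pid), []))
        for a in assignments:
            f_day = fitting_by_order.get((int(pid), a.order_day)) \
                if a.order_day is not None else None
            res = filter_return_window(a, f_day, min_days, max_days)
            rows.append(dataclasses.asdict(res))
    return pd.DataFrame(rows, columns=cols)
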