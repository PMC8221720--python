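"""Battery-order persistence and medication possession ratio.

Battery orders are treated as prescription refills: each order dispenses a
nominal supply of ``dose_days`` (D_dose, default 183 days = 6 months of
full-time use), and a patient is allowed a lapse of up to ``gap_days``
(G_acc, default 365 days = 12 months) beyond supply exhaustion before being
deemed to have discontinued.  With t_last the time of the most recent
battery order strictly before the evaluation time T (both measured in days
from the fitting, whose own battery order sits at t = 0), a patient is

    persistent at T  iff  T < t_last + D_dose + G_acc.

Because every history contains the fitting-day order, the smallest T at
which anyone can be non-persistent is D_dose + G_acc (548 days = 18 months
under the package day convention).  Cohort persistence at T is the fraction
persistent among patients who survived through [fitting, fitting + T).

The medication possession ratio (MPR) is the number of days with supply on
hand divided by the days observed; overlapping supplies are unioned, never
double-counted.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class PersistenceParams:
    """D_dose, G_acc and the evaluation horizon T, in days."""
    dose_days: int = 183
    gap_days: int = 365
    eval_days: int = 730

    def __post_init__(self):
        for name in ("dose_days", "gap_days", "eval_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def min_nonpersistent_day(self) -> int:
        """Smallest T at which a fitting-day-only history fails."""
        return self.dose_days + self.gap_days


@dataclasses.dataclass
class BatteryOrderHistory:
    """Sorted, deduplicated battery-order days anchored to a fitting date.

    ``order_days`` are absolute days and must contain the fitting-day order
    itself (the fitting-date proxy is the first battery order).
    """
    patient_id: int
    fitting_day: int
    order_days: np.ndarray

    def __post_init__(self):
        days = np.unique(np.asarray(self.order_days, dtype=np.int64))
        if days.size == 0:
            raise ValueError(f"patient {self.patient_id}: empty order history")
        if days[0] != self.fitting_day:
            raise ValueError(
                f"patient {self.patient_id}: first order day {days[0]} does "
                f"not equal fitting day {self.fitting_day}")
        self.order_days = days

    @property
    def relative_days(self) -> np.ndarray:
        return self.order_days - self.fitting_day


def is_persistent(history: BatteryOrderHistory, params: PersistenceParams,
                  t_eval: Optional[int] = None) -> bool:
    """Apply T < t_last + D_dose + G_acc with strict 'before T' semantics.

    An order on day T itself does not rescue persistence at T.
    """
    T = params.eval_days if t_eval is None else int(t_eval)
    if T <= 0:
        raise ValueError(f"t_eval must be positive, got {T}")
    rel = history.relative_days
    before = rel[rel < T]
    t_last = int(before.max())        # rel contains 0, so never empty for T > 0
    return T < t_last + params.dose_days + params.gap_days


@dataclasses.dataclass
class CohortPersistence:
    proportion: float
    n_included: int
    n_excluded_death: int
    n_excluded_implausible: int = 0


def cohort_persistence(histories: Sequence[BatteryOrderHistory],
                       demographics: pd.DataFrame,
                       params: PersistenceParams,
                       t_eval: Optional[int] = None) -> CohortPersistence:
    """Fraction persistent among patients surviving through the window.

    ``demographics`` is a merged per-patient table with columns
    ``patient_id``, ``death_day`` and (optionally) ``implausible``.
    Patients flagged implausible are excluded from this survival-dependent
    analysis; patients who died within [fitting, fitting + T) are excluded.
    """
    T = params.eval_days if t_eval is None else int(t_eval)
    demo = demographics.set_index("patient_id")
    death_map = demo["death_day"].to_dict() if "death_day" in demo else {}
    implaus_map = (demo["implausible"].to_dict()
                   if "implausible" in demo else {})
    n_inc = n_dead = n_impl = n_pers = 0
    for h in histories:
        if implaus_map.get(h.patient_id, False):
            n_impl += 1
            continue
        d = death_map.get(h.patient_id)
        if d is not None and not pd.isna(d) and d < h.fitting_day + T:
            n_dead += 1
            continue
        n_inc += 1
        n_pers += is_persistent(h, params, T)
    if n_inc == 0:
        raise ValueError("cohort_persistence: no patients left after exclusions")
    return CohortPersistence(proportion=n_pers / n_inc, n_included=n_inc,
                             n_excluded_death=n_dead,
                             n_excluded_implausible=n_impl)


def medication_possession_ratio(history: BatteryOrderHistory,
                                window_days: int,
                                params: PersistenceParams) -> float:
    """Days covered by the union of supply intervals, over days observed.

    Each order at relative day t contributes supply [t, t + dose_days),
    intersected with the observation window [0, window_days).  The ratio
    can exceed 1 only if capping is applied by the caller; the raw union
    never exceeds 1.
    """
    if window_days <= 0:
        raise ValueError(f"window_days must be positive, got {window_days}")
    rel = history.relative_days
    rel = rel[(rel < window_days)]
    covered = 0
    cover_end = 0          # union sweep over sorted starts
    for t in rel:
        start = max(int(t), cover_end)
        end = min(int(t) + params.dose_days, window_days)
        if end > start:
            covered += end - start
            cover_end = end
        else:
            cover_end = max(cover_end, end)
    return covered / window_days


def persistence_curve(histories: Sequence[BatteryOrderHistory],
                      demographics: pd.DataFrame, params: PersistenceParams,
                      t_grid: Sequence[int]) -> list[tuple[int, float, int]]:
    """Cohort persistence at each t, with the death window tied to that t.

    Returns (t, proportion, n_included) triples.  t_grid must ascend.
    """
    grid = list(t_grid)
    if grid != sorted(grid):
        raise ValueError("t_grid must be ascending")
    out = []
    for t in grid:
        cp = cohort_persistence(histories, demographics, params, t_eval=t)
        out.append((int(t), cp.proportion, cp.n_included))
    return out


# ---------------------------------------------------------------------------
# vectorized helpers used by the pipeline at cohort scale


def histories_from_tables(fittings: pd.DataFrame,
                          battery_orders: pd.DataFrame
                          ) -> list[BatteryOrderHistory]:
    """Build per-patient histories from fitting and battery-order tables.

    Patients without an assigned fitting date are skipped (no anchor);
    battery orders before the fitting day are ignored.
    """
    fit = fittings.dropna(subset=["fitting_day"])
    fit_map = dict(zip(fit["patient_id"].astype(int),
                       fit["fitting_day"].astype(int)))
    orders = battery_orders[battery_orders["patient_id"].isin(fit_map)]
    grouped = orders.groupby("patient_id")["order_day"]
    out = []
    for pid, days in grouped:
        f = fit_map[int(pid)]
        arr = np.asarray(days, dtype=np.int64)
        arr = arr[arr >= f]
        out.append(BatteryOrderHistory(patient_id=int(pid), fitting_day=f,
                                       order_days=arr))
    return out


def persistence_flags(fittings: pd.DataFrame, battery_orders: pd.DataFrame,
                      params: PersistenceParams,
                      t_eval: Optional[int] = None) -> pd.Series:
    """Per-patient persistence flag, computed without building objects.

    Index = patient id (patients with an assigned fitting), value = bool.
    Agrees with :func:`is_persistent` applied per history; the scalar path
    is the reference, this one is the throughput path.
    """
    T = params.eval_days if t_eval is None else int(t_eval)
    fit = fittings.dropna(subset=["fitting_day"])[["patient_id", "fitting_day"]]
    merged = battery_orders.merge(fit, on="patient_id", how="inner")
    rel = merged["order_day"].astype(np.int64) - merged["fitting_day"].astype(np.int64)
    ok = (rel >= 0) & (rel < T)
    t_last = rel[ok].groupby(merged.loc[ok, "patient_id"]).max()
    t_last = t_last.reindex(fit["patient_id"].astype(int), fill_value=0)
    return T < t_last + params.dose_days + params.gap_days
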