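"""Hearing-care event detection, the fitting-date proxy, and user type.

There is no single procedural code for a hearing-aid fitting, so two
conventions are implemented here:

* a *hearing-care event* occurs on any date on which at least one code from
  a configurable hearing-care code list appears in the outpatient diagnosis
  or procedure stream; all records sharing a date form one event
  (one appointment, possibly multiple procedures);
* the *fitting date* of an HA order is proxied by the date of the first
  battery order on/after the HA order, accepted only when its lag is at
  most ``max_lag`` days (default 180).  Battery orders strictly before the
  HA order belong to a prior device and are ignored.

User type is ``experienced`` iff any HA order strictly precedes the index
order (a second order on the same day does not count as prior).
"""

from __future__ import annotations

import dataclasses
import pathlib
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .morbidity import normalize_icd9

DEFAULT_MAX_LAG = 180


def _norm_code(code: str) -> str:
    return normalize_icd9(code)   # same canonical form: upper, no dot


@dataclasses.dataclass(frozen=True)
class CodeList:
    procedural: frozenset[str]
    icd9: frozenset[str]
    icd10: frozenset[str]
    fitting: frozenset[str]

    def __post_init__(self):
        if not self.fitting <= self.procedural:
            raise ValueError("fitting-indicating codes must be a subset of "
                             "procedural codes")

    @property
    def diagnostic(self) -> frozenset[str]:
        return self.icd9 | self.icd10

    @classmethod
    def from_csv(cls, path: str | pathlib.Path | None = None) -> "CodeList":
        """Load a code list CSV with columns code, code_system, fitting_flag."""
        if path is None:
            path = resources.files("audiocohort.data") / "hearing_care_codes_toy.csv"
        df = pd.read_csv(str(path), dtype={"code": str})
        sets: dict[str, set[str]] = {"CPT": set(), "HCPCS": set(),
                                     "ICD9": set(), "ICD10": set()}
        fitting = set()
        for code, system, flag in df.itertuples(index=False):
            norm = _norm_code(code)
            system = str(system).upper()
            if system not in sets:
                raise ValueError(f"unknown code_system {system!r} for {code!r}")
            sets[system].add(norm)
            if int(flag):
                fitting.add(norm)
        return cls(procedural=frozenset(sets["CPT"] | sets["HCPCS"]),
                   icd9=frozenset(sets["ICD9"]), icd10=frozenset(sets["ICD10"]),
                   fitting=frozenset(fitting))


@dataclasses.dataclass
class CareEvent:
    patient_id: int
    day: int
    codes: frozenset[str]


@dataclasses.dataclass
class FittingAssignment:
    patient_id: int
    ha_order_day: int
    fitting_day: Optional[int]
    lag: Optional[int]


def detect_care_events(diagnoses: pd.DataFrame, procedures: pd.DataFrame,
                       codes: CodeList) -> list[CareEvent]:
    """One event per (patient, date) carrying all matching codes that day."""
    frames = []
    if not diagnoses.empty:
        d = diagnoses[["patient_id", "icd_code", "day"]].rename(
            columns={"icd_code": "code"})
        d["code"] = d["code"].astype(str).map(_norm_code)
        frames.append(d[d["code"].isin(codes.diagnostic)])
    if not procedures.empty:
        p = procedures[["patient_id", "proc_code", "day"]].rename(
            columns={"proc_code": "code"})
        p["code"] = p["code"].astype(str).map(_norm_code)
        frames.append(p[p["code"].isin(codes.procedural)])
    if not frames:
        return []
    hits = pd.concat(frames, ignore_index=True)
    if hits.empty:
        return []
    grouped = hits.groupby(["patient_id", "day"], sort=True)["code"]
    return [CareEvent(patient_id=int(pid), day=int(day),
                      codes=frozenset(code_group))
            for (pid, day), code_group in grouped]


def assign_fitting_date(ha_order_day: int, battery_order_days: Sequence[int],
                        max_lag: int = DEFAULT_MAX_LAG,
                        patient_id: int = -1) -> FittingAssignment:
    """First battery order on/after the HA order, if within ``max_lag`` days."""
    days = list(battery_order_days)
    if days != sorted(days):
        raise ValueError("battery_order_days must be sorted ascending")
    for day in days:
        if day >= ha_order_day:
            lag = int(day - ha_order_day)
            if lag <= max_lag:
                return FittingAssignment(patient_id, int(ha_order_day),
                                         int(day), lag)
            break
    return FittingAssignment(patient_id, int(ha_order_day), None, None)


def classify_user_type(ha_order_days: Sequence[int], index_order_day: int) -> str:
    """``experienced`` iff any order strictly precedes the index order."""
    days = list(ha_order_days)
    if index_order_day not in days:
        raise ValueError(f"index order day {index_order_day} not among the "
                         f"patient's HA orders")
    return "experienced" if any(d < index_order_day for d in days) else "new"


# ---------------------------------------------------------------------------
# vectorized fitting assignment used by the pipeline


def fitting_table(ha_orders: pd.DataFrame, battery_orders: pd.DataFrame,
                  max_lag: int = DEFAULT_MAX_LAG) -> pd.DataFrame:
    """Per-patient fitting assignment anchored to the first HA order.

    Returns columns patient_id, ha_order_day, fitting_day, lag; fitting_day
    and lag are NaN when no battery order lands within the window.
    """
    from .cohort import first_ha_orders

    first = first_ha_orders(ha_orders)[["patient_id", "order_day"]].rename(
        columns={"order_day": "ha_order_day"})
    if first.empty:
        return pd.DataFrame(columns=["patient_id", "ha_order_day",
                                     "fitting_day", "lag"])
    bat = battery_orders.merge(first, on="patient_id", how="inner")
    bat = bat[bat["order_day"] >= bat["ha_order_day"]]
    first_bat = (bat.groupby("patient_id")["order_day"].min()
                 .rename("fitting_day"))
    out = first.merge(first_bat, on="patient_id", how="left")
    out["lag"] = out["fitting_day"] - out["ha_order_day"]
    beyond = out["lag"] > max_lag
    out.loc[beyond, ["fitting_day", "lag"]] = np.nan
    return out
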