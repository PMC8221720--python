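"""Merging per-station demographic records and survival-based exclusions.

Patients seen at more than one station carry one demographic record per
station.  Records are merged by taking the modal value of each field; when
no strict majority exists the value from the earliest-dated source record
wins (a deterministic, auditable tie-break).  Any disagreement across
records sets the ``inconsistent`` flag.

A merged record is ``implausible`` when the date of death precedes the date
of birth or the first hearing-aid order; such patients are excluded from
analyses requiring age or survival information.  "Died within t days of
fitting" uses the half-open interval [fitting, fitting + t).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Optional, Sequence

import numpy as np
import pandas as pd

_MERGE_FIELDS = ("birth_day", "death_day", "gender")


@dataclasses.dataclass
class PatientDemographics:
    patient_id: int
    birth_day: Optional[int]
    death_day: Optional[int]
    gender: str
    n_source_records: int = 1
    inconsistent: bool = False
    implausible: bool = False


def _modal(values: Sequence, record_order: Sequence[int]):
    """Most frequent value; ties broken by earliest source record.

    ``record_order`` gives each record's rank by record date (0 = earliest).
    Missing values (None/NaN) participate like any other value.
    """
    keyed = [(None if _is_na(v) else v) for v in values]
    counts = Counter(keyed)
    best = max(counts.values())
    tied = {v for v, c in counts.items() if c == best}
    if len(tied) == 1:
        return next(iter(tied))
    for _, v in sorted(zip(record_order, keyed)):
        if v in tied:
            return v
    raise AssertionError("unreachable")


def _is_na(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA


def merge_demographic_records(records: Sequence[dict]) -> PatientDemographics:
    """Merge one patient's per-station rows into a single record.

    Each record is a mapping with keys ``patient_id``, ``birth_day``,
    ``death_day``, ``gender`` and optionally ``record_day`` (used only for
    tie-breaking; records without one are ranked last, in input order).
    """
    if not records:
        raise ValueError("merge_demographic_records: empty record list")
    ids = {r["patient_id"] for r in records}
    if len(ids) != 1:
        raise ValueError(f"merge_demographic_records: mixed patient ids {sorted(ids)}")
    record_days = [r.get("record_day") for r in records]
    order = _rank_by_day(record_days)
    merged = {}
    inconsistent = False
    for field in _MERGE_FIELDS:
        vals = [r.get(field) for r in records]
        keyed = [None if _is_na(v) else v for v in vals]
        if len(set(keyed)) > 1:
            inconsistent = True
        merged[field] = _modal(vals, order)
    return PatientDemographics(
        patient_id=next(iter(ids)),
        birth_day=None if merged["birth_day"] is None else int(merged["birth_day"]),
        death_day=None if merged["death_day"] is None else int(merged["death_day"]),
        gender=merged["gender"],
        n_source_records=len(records),
        inconsistent=inconsistent,
    )


def _rank_by_day(record_days: Sequence) -> list[int]:
    keys = [(1, i) if _is_na(d) else (0, d, i) for i, d in enumerate(record_days)]
    ranks = sorted(range(len(keys)), key=lambda i: keys[i])
    out = [0] * len(keys)
    for rank, i in enumerate(ranks):
        out[i] = rank
    return out


def flag_implausible(demographics: PatientDemographics,
                     first_order_day: int) -> PatientDemographics:
    """Set the implausible flag: death strictly before birth or first order.

    A death on the same day as the first order is allowed (the rule reads
    "preceded" strictly).
    """
    d = dataclasses.replace(demographics)
    death = d.death_day
    d.implausible = death is not None and (
        (d.birth_day is not None and death < d.birth_day)
        or death < first_order_day)
    return d


def survives_through(demographics: PatientDemographics, fitting_day: int,
                     t_eval: int) -> bool:
    """True iff the patient did not die within [fitting, fitting + t_eval)."""
    death = demographics.death_day
    return death is None or death >= fitting_day + t_eval


# ---------------------------------------------------------------------------
# table-level merge used by the pipeline


def merge_demographics_table(demographics: pd.DataFrame) -> pd.DataFrame:
    """One merged row per patient, with consistency flags.

    Fast path: patients whose records agree on every field are taken
    verbatim; only disagreeing groups go through the modal/tie-break logic.
    """
    cols = ["patient_id", "birth_day", "death_day", "gender",
            "n_source_records", "inconsistent"]
    if demographics.empty:
        return pd.DataFrame(columns=cols)
    df = demographics.copy()
    grouped = df.groupby("patient_id", sort=True)
    nun = grouped[list(_MERGE_FIELDS)].nunique(dropna=False)
    n_records = grouped.size()
    consistent_ids = nun.index[(nun <= 1).all(axis=1)]
    firsts = grouped.first().loc[consistent_ids]
    out = pd.DataFrame({
        "patient_id": consistent_ids.astype(int),
        "birth_day": firsts["birth_day"].values,
        "death_day": firsts["death_day"].values,
        "gender": firsts["gender"].values,
        "n_source_records": n_records.loc[consistent_ids].values,
        "inconsistent": False,
    })
    odd_ids = nun.index.difference(consistent_ids)
    rows = []
    for pid in odd_ids:
        recs = df[df["patient_id"] == pid].to_dict("records")
        m = merge_demographic_records(recs)
        rows.append({"patient_id": m.patient_id, "birth_day": m.birth_day,
                     "death_day": m.death_day, "gender": m.gender,
                     "n_source_records": m.n_source_records,
                     "inconsistent": m.inconsistent})
    if rows:
        extra = pd.DataFrame(rows)
        for c in ("birth_day", "death_day"):
            extra[c] = pd.to_numeric(extra[c], errors="coerce")
        out = pd.concat([out, extra], ignore_index=True)
    out = out.sort_values("patient_id").reset_index(drop=True)
    out["death_day"] = pd.to_numeric(out["death_day"], errors="coerce")
    out["birth_day"] = pd.to_numeric(out["birth_day"], errors="coerce")
    return out[cols]


def flag_implausible_table(merged: pd.DataFrame,
                           first_order_days: pd.Series) -> pd.DataFrame:
    """Vectorized implausibility flag over the merged table."""
    out = merged.copy()
    order_day = out["patient_id"].map(first_order_days)
    death = out["death_day"]
    birth = out["birth_day"]
    out["implausible"] = (death.notna() &
                          ((birth.notna() & (death < birth)) |
                           (order_day.notna() & (death < order_day))))
    return out
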