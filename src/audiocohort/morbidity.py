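"""Multimorbidity indexing from ICD-9 diagnosis streams.

The index follows the Chronic Condition Indicator (CCI) scheme: each ICD-9
code maps to a chronic/non-chronic flag and one of 18 body systems.  A body
system counts toward the index when the patient has at least ``min_codes``
(default 2) chronic-flagged codes in that system within the lookback window
(default the 12 months before the index date, half-open so codes on the
index date itself are excluded).  Hearing-loss codes in group 389.XX are
removed before counting so the index stays sensitive to other conditions in
the nervous-system/sense-organ system that every hearing-aid patient
otherwise trips.  The resulting index ranges from 0 to 18.

The shipped CCI table is a small synthetic stand-in (``cci_map_toy.csv``)
with representative codes for each body system; analyses of real data should
load the full AHRQ table via :func:`load_cci_map`.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

N_BODY_SYSTEMS = 18


def normalize_icd9(code: str) -> str:
    """Canonical form for matching: uppercase, no dot, no whitespace."""
    return str(code).strip().upper().replace(".", "")


@dataclasses.dataclass(frozen=True)
class CCIMap:
    """Lookup from normalized ICD-9 code to (chronic flag, body system).

    Unknown codes resolve to non-chronic with no body system.
    """

    entries: Mapping[str, tuple[bool, int]]

    def lookup(self, code: str) -> tuple[bool, Optional[int]]:
        hit = self.entries.get(normalize_icd9(code))
        if hit is None:
            return (False, None)
        return hit

    def chronic_codes_for_system(self, system: int) -> list[str]:
        return sorted(c for c, (chronic, s) in self.entries.items()
                      if chronic and s == system)


def load_cci_map(path: str | pathlib.Path | None = None) -> CCIMap:
    """Read a CCI table CSV with columns ``code, chronic, body_system``."""
    if path is None:
        path = resources.files("audiocohort.data") / "cci_map_toy.csv"
    df = pd.read_csv(str(path), dtype={"code": str})
    entries = {}
    for code, chronic, system in df.itertuples(index=False):
        system = int(system)
        if not 1 <= system <= N_BODY_SYSTEMS:
            raise ValueError(f"body_system {system} outside 1..{N_BODY_SYSTEMS} "
                             f"for code {code!r}")
        entries[normalize_icd9(code)] = (bool(int(chronic)), system)
    return CCIMap(entries=entries)


@dataclasses.dataclass
class MultimorbidityResult:
    patient_id: Optional[int]
    index: int
    system_counts: dict[int, int]
    window: tuple[int, int]


@dataclasses.dataclass(frozen=True)
class ConditionDefinition:
    """A named condition as a set of ICD-9 prefixes and/or category ranges.

    ``prefixes`` match on the normalized code string (``"250"`` matches
    ``250.01``); ``ranges`` are inclusive three-digit-category bounds
    (``(360, 379)`` matches any code whose numeric category falls inside).
    """

    name: str
    prefixes: frozenset[str] = frozenset()
    ranges: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if not self.prefixes and not self.ranges:
            raise ValueError(f"condition {self.name!r}: empty code set")

    def matches(self, code: str) -> bool:
        norm = normalize_icd9(code)
        for p in self.prefixes:
            if norm.startswith(normalize_icd9(p)):
                return True
        cat = norm[:3]
        if cat.isdigit():
            cat_num = int(cat)
            for lo, hi in self.ranges:
                if lo <= cat_num <= hi:
                    return True
        return False


def default_condition_definitions() -> dict[str, ConditionDefinition]:
    """Illustrative comorbidity definitions shipped with the package.

    Note: the arthritis/vision category ranges reproduce a published
    transposition (see docs/methods.md); override with custom definitions
    for substantive use.
    """
    path = resources.files("audiocohort.data") / "condition_definitions.json"
    raw = json.loads(path.read_text())
    return {
        name: ConditionDefinition(
            name=name,
            prefixes=frozenset(spec.get("prefixes", [])),
            ranges=tuple((int(lo), int(hi)) for lo, hi in spec.get("ranges", [])),
        )
        for name, spec in raw.items()
    }


def _as_code_day_pairs(diagnoses) -> list[tuple[str, int]]:
    if isinstance(diagnoses, pd.DataFrame):
        code_col = "icd_code" if "icd_code" in diagnoses.columns else "code"
        return list(zip(diagnoses[code_col].astype(str), diagnoses["day"].astype(int)))
    return [(str(c), int(d)) for c, d in diagnoses]


def multimorbidity_index(diagnoses, index_day: int, cci: CCIMap,
                         window_days: int = 365, min_codes: int = 2,
                         exclude_prefix: str = "389",
                         patient_id: Optional[int] = None) -> MultimorbidityResult:
    """Count body systems with >= ``min_codes`` chronic codes in-window.

    The window is half-open: codes dated in
    ``[index_day - window_days, index_day)`` are counted; codes on the index
    day are not.  Codes beginning with ``exclude_prefix`` are removed first.
    """
    start = index_day - window_days
    excl = normalize_icd9(exclude_prefix)
    counts: dict[int, int] = {}
    for code, day in _as_code_day_pairs(diagnoses):
        if not start <= day < index_day:
            continue
        norm = normalize_icd9(code)
        if excl and norm.startswith(excl):
            continue
        chronic, system = cci.entries.get(norm, (False, None))
        if chronic:
            counts[system] = counts.get(system, 0) + 1
    index = sum(1 for c in counts.values() if c >= min_codes)
    return MultimorbidityResult(patient_id=patient_id, index=index,
                                system_counts=counts, window=(start, index_day))


def has_condition(diagnoses, definition: ConditionDefinition,
                  before_day: int) -> bool:
    """True iff >= 1 code matching the definition strictly before the day."""
    return any(day < before_day and definition.matches(code)
               for code, day in _as_code_day_pairs(diagnoses))


def had_inpatient_stay(inpatient_stays, before_day: int) -> bool:
    """True iff any admission date falls strictly before the given day."""
    if isinstance(inpatient_stays, pd.DataFrame):
        if inpatient_stays.empty:
            return False
        return bool((inpatient_stays["admit_day"].astype(int) < before_day).any())
    return any(int(d) < before_day for d in inpatient_stays)


# ---------------------------------------------------------------------------
# vectorized table-level computation used by the pipeline


def multimorbidity_table(diagnoses: pd.DataFrame, index_days: pd.Series,
                         cci: CCIMap, window_days: int = 365,
                         min_codes: int = 2,
                         exclude_prefix: str = "389") -> pd.DataFrame:
    """Per-patient multimorbidity index for every patient in ``index_days``.

    ``index_days`` maps patient id -> index date (typically the first HA
    order day).  Patients with no qualifying codes get index 0.
    """
    out = pd.DataFrame({"patient_id": index_days.index.astype(int),
                        "mm_index": 0})
    if diagnoses.empty:
        return out
    df = diagnoses[["patient_id", "icd_code", "day"]].copy()
    df["index_day"] = df["patient_id"].map(index_days)
    df = df.dropna(subset=["index_day"])
    df["day"] = df["day"].astype(int)
    df["index_day"] = df["index_day"].astype(int)
    in_window = ((df["day"] >= df["index_day"] - window_days) &
                 (df["day"] < df["index_day"]))
    df = df[in_window]
    norm = (df["icd_code"].astype(str).str.strip().str.upper()
            .str.replace(".", "", regex=False))
    excl = normalize_icd9(exclude_prefix)
    if excl:
        df = df[~norm.str.startswith(excl)]
        norm = norm[df.index]
    flags = norm.map({c: (ch, s) for c, (ch, s) in cci.entries.items()})
    known = flags.notna()
    df = df[known]
    if df.empty:
        return out
    chronic = flags[known].map(lambda t: t[0]).astype(bool)
    system = flags[known].map(lambda t: t[1]).astype(int)
    df = df.assign(system=system)[chronic.values]
    per_system = (df.groupby(["patient_id", "system"]).size()
                  .reset_index(name="n_codes"))
    qualifying = per_system[per_system["n_codes"] >= min_codes]
    idx = qualifying.groupby("patient_id").size()
    out["mm_index"] = out["patient_id"].map(idx).fillna(0).astype(int)
    return out


def condition_flags_table(diagnoses: pd.DataFrame, index_days: pd.Series,
                          definitions: Mapping[str, ConditionDefinition]
                          ) -> pd.DataFrame:
    """Per-patient presence flags for each named condition before the index."""
    out = pd.DataFrame({"patient_id": index_days.index.astype(int)})
    if diagnoses.empty:
        for name in definitions:
            out[f"has_{name}"] = False
        return out
    df = diagnoses[["patient_id", "icd_code", "day"]].copy()
    df["index_day"] = df["patient_id"].map(index_days)
    df = df.dropna(subset=["index_day"])
    df = df[df["day"].astype(int) < df["index_day"].astype(int)]
    codes = df["icd_code"].astype(str)
    for name, definition in definitions.items():
        unique_codes = codes.unique()
        matching = {c for c in unique_codes if definition.matches(c)}
        hit_patients = set(df.loc[codes.isin(matching), "patient_id"])
        out[f"has_{name}"] = out["patient_id"].isin(hit_patients)
    return out


def inpatient_flags_table(inpatient: pd.DataFrame,
                          index_days: pd.Series) -> pd.DataFrame:
    out = pd.DataFrame({"patient_id": index_days.index.astype(int)})
    if inpatient.empty:
        out["had_inpatient"] = False
        return out
    df = inpatient[["patient_id", "admit_day"]].copy()
    df["index_day"] = df["patient_id"].map(index_days)
    df = df.dropna(subset=["index_day"])
    prior = df[df["admit_day"].astype(int) < df["index_day"].astype(int)]
    out["had_inpatient"] = out["patient_id"].isin(set(prior["patient_id"]))
    return out
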