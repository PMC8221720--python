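"""Audiogram cleaning, validity, averaging, and pure-tone averages.

Raw audiometric entries are free text.  Cleaning maps each entry to a dB HL
value or to missing, with a provenance tag:

* above-limit tokens (``NR``, ``120+``, ``>120``) become 120 dB,
  tagged ``ceiling_substituted``;
* ambiguous tokens (``DNT``, ``CNT``, ``--``), unparsable text, numbers not
  divisible by 5, and numbers outside [-10, 120] become missing,
  tagged ``set_missing``;
* everything else passes through unchanged (``as_entered``); empty entries
  stay missing with tag ``as_entered`` (nothing was altered).

An audiogram is valid when, after cleaning, all eight (ear, frequency)
cells at 0.5/1/2/4 kHz are numeric (120 dB included).  The four-frequency
pure-tone average (4F-PTA) is the per-ear mean of those four thresholds;
the bilateral 4F-PTA is the mean of the two ear PTAs.  A clinically
relevant asymmetry is an absolute left-right 4F-PTA difference >= 15 dB HL.
Multiple valid audiograms for one patient are averaged cell-wise before the
PTA is computed (a cell is missing only if missing in every audiogram).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import AUDIO_FREQS

PTA_FREQS = (500, 1000, 2000, 4000)
EARS = ("left", "right")

CEILING_TOKENS = frozenset({"NR", "120+", ">120"})
MISSING_TOKENS = frozenset({"DNT", "CNT", "--"})
CEILING_DB = 120.0
DB_MIN, DB_MAX = -10.0, 120.0

AS_ENTERED = "as_entered"
CEILING_SUBSTITUTED = "ceiling_substituted"
SET_MISSING = "set_missing"


@dataclasses.dataclass
class RawAudiogram:
    patient_id: int
    exam_day: int
    #: (ear, frequency) -> raw text entry; absent keys mean untested
    entries: dict[tuple[str, int], str]


@dataclasses.dataclass
class CleanAudiogram:
    patient_id: int
    exam_day: int
    values: dict[tuple[str, int], float]       # NaN = missing
    provenance: dict[tuple[str, int], str]


@dataclasses.dataclass
class PTASummary:
    patient_id: int
    left: float
    right: float
    bilateral: float
    asymmetric: bool
    worse_ear: str          # "left" | "right" | "none"


def clean_entry(entry: str,
                ceiling_tokens: frozenset[str] = CEILING_TOKENS,
                missing_tokens: frozenset[str] = MISSING_TOKENS
                ) -> tuple[float, str]:
    """Map one raw entry to (value-or-NaN, provenance tag). Never raises."""
    text = str(entry).strip()
    if not text:
        return (math.nan, AS_ENTERED)
    upper = text.upper()
    if upper in ceiling_tokens:
        return (CEILING_DB, CEILING_SUBSTITUTED)
    if upper in missing_tokens:
        return (math.nan, SET_MISSING)
    try:
        value = float(text)
    except ValueError:
        return (math.nan, SET_MISSING)
    if value % 5 != 0 or not DB_MIN <= value <= DB_MAX:
        return (math.nan, SET_MISSING)
    return (value, AS_ENTERED)


def clean_audiogram(raw: RawAudiogram, **token_sets) -> CleanAudiogram:
    values, provenance = {}, {}
    for key in ((ear, f) for ear in EARS for f in AUDIO_FREQS):
        entry = raw.entries.get(key, "")
        values[key], provenance[key] = clean_entry(entry, **token_sets)
    return CleanAudiogram(patient_id=raw.patient_id, exam_day=raw.exam_day,
                          values=values, provenance=provenance)


def is_valid(clean: CleanAudiogram) -> bool:
    """Valid iff all eight 0.5/1/2/4 kHz cells are numeric, both ears."""
    return all(not math.isnan(clean.values.get((ear, f), math.nan))
               for ear in EARS for f in PTA_FREQS)


def average_audiograms(cleans: Sequence[CleanAudiogram]) -> CleanAudiogram:
    """Cell-wise mean across audiograms; missing only if missing in all."""
    if not cleans:
        raise ValueError("average_audiograms: empty list")
    pids = {c.patient_id for c in cleans}
    if len(pids) != 1:
        raise ValueError(f"average_audiograms: mixed patients {sorted(pids)}")
    values, provenance = {}, {}
    for key in ((ear, f) for ear in EARS for f in AUDIO_FREQS):
        cell = [c.values.get(key, math.nan) for c in cleans]
        finite = [v for v in cell if not math.isnan(v)]
        if finite:
            values[key] = float(np.mean(finite))
            tags = {c.provenance.get(key) for c, v in zip(cleans, cell)
                    if not math.isnan(v)}
            provenance[key] = (CEILING_SUBSTITUTED if CEILING_SUBSTITUTED in tags
                               else AS_ENTERED)
        else:
            values[key] = math.nan
            provenance[key] = cleans[0].provenance.get(key, AS_ENTERED)
    return CleanAudiogram(patient_id=cleans[0].patient_id,
                          exam_day=min(c.exam_day for c in cleans),
                          values=values, provenance=provenance)


def compute_4f_pta(clean: CleanAudiogram,
                   asymmetry_threshold: float = 15.0) -> PTASummary:
    if not is_valid(clean):
        raise ValueError(f"patient {clean.patient_id}: audiogram invalid "
                         "(missing 0.5/1/2/4 kHz thresholds)")
    left = float(np.mean([clean.values[("left", f)] for f in PTA_FREQS]))
    right = float(np.mean([clean.values[("right", f)] for f in PTA_FREQS]))
    diff = left - right
    asymmetric = abs(diff) >= asymmetry_threshold
    worse = "none" if not asymmetric else ("left" if diff > 0 else "right")
    return PTASummary(patient_id=clean.patient_id, left=left, right=right,
                      bilateral=(left + right) / 2.0, asymmetric=asymmetric,
                      worse_ear=worse)


# ---------------------------------------------------------------------------
# vectorized table-level cleaning used by the pipeline

_EAR_PREFIX = {"left": "l", "right": "r"}


def clean_audiometry_table(audiometry: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Clean every entry column; returns (numeric table, cleaning log).

    The log counts, per provenance class, how many entries were ceiling-
    substituted or set missing — the substrate of cleaning-conservation
    checks against a known injection log.
    """
    out = audiometry[["patient_id", "exam_day"]].copy()
    log = {CEILING_SUBSTITUTED: 0, SET_MISSING: 0, AS_ENTERED: 0}
    for ear in EARS:
        for f in AUDIO_FREQS:
            col = f"{_EAR_PREFIX[ear]}{f}"
            raw = audiometry[col].astype(str).str.strip() if col in audiometry \
                else pd.Series("", index=audiometry.index)
            upper = raw.str.upper()
            numeric = pd.to_numeric(raw, errors="coerce")
            ok = numeric.notna() & (numeric % 5 == 0) & \
                numeric.between(DB_MIN, DB_MAX)
            ceiling = upper.isin(CEILING_TOKENS)
            empty = raw == ""
            values = numeric.where(ok).astype(float)
            values[ceiling] = CEILING_DB
            out[col] = values
            log[CEILING_SUBSTITUTED] += int(ceiling.sum())
            log[SET_MISSING] += int((~ok & ~ceiling & ~empty).sum())
            log[AS_ENTERED] += int((ok | empty).sum())
    return out, log


def pta_summary_table(clean: pd.DataFrame,
                      asymmetry_threshold: float = 15.0) -> pd.DataFrame:
    """Per-patient PTA summary from a cleaned audiometry table.

    Valid audiograms are averaged cell-wise per patient, then the 4F-PTA,
    asymmetry flag, and worse ear are derived.  Patients with no valid
    audiogram are omitted.
    """
    pta_cols = {ear: [f"{_EAR_PREFIX[ear]}{f}" for f in PTA_FREQS]
                for ear in EARS}
    required = pta_cols["left"] + pta_cols["right"]
    if clean.empty:
        return pd.DataFrame(columns=["patient_id", "pta_left", "pta_right",
                                     "pta_bilateral", "asymmetric",
                                     "worse_ear", "n_audiograms"])
    valid = clean[clean[required].notna().all(axis=1)]
    cell_cols = [f"{_EAR_PREFIX[e]}{f}" for e in EARS for f in AUDIO_FREQS]
    averaged = valid.groupby("patient_id")[cell_cols].mean()
    n_audio = valid.groupby("patient_id").size()
    left = averaged[pta_cols["left"]].mean(axis=1)
    right = averaged[pta_cols["right"]].mean(axis=1)
    diff = left - right
    asym = diff.abs() >= asymmetry_threshold
    worse = np.where(~asym, "none", np.where(diff > 0, "left", "right"))
    return pd.DataFrame({
        "patient_id": averaged.index.astype(int),
        "pta_left": left.values, "pta_right": right.values,
        "pta_bilateral": ((left + right) / 2.0).values,
        "asymmetric": asym.values, "worse_ear": worse,
        "n_audiograms": n_audio.values,
    }).reset_index(drop=True)
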