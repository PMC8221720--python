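"""Raw-cohort container and on-disk round trip.

A :class:`RawCohort` bundles the seven relational tables of a VA-style
hearing-aid dataset (demographics, outpatient diagnoses, outpatient
procedures, inpatient stays, audiometry, hearing-aid orders, battery orders,
IOI-HA surveys), keyed by a shared patient identifier.  In memory every date
column holds integer days from :data:`audiocohort.units.EPOCH`; on disk the
CSV writer renders them as ISO-8601 dates (parquet keeps integer days).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Iterator

import pandas as pd

from .units import EPOCH

AUDIO_FREQS = (250, 500, 1000, 1500, 2000, 3000, 4000, 6000, 8000)
AUDIO_COLS = tuple(f"{ear}{f}" for ear in ("l", "r") for f in AUDIO_FREQS)

TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "demographics": ("patient_id", "station_id", "record_day", "birth_day",
                     "death_day", "gender"),
    "diagnoses_outpatient": ("patient_id", "icd_code", "day"),
    "procedures_outpatient": ("patient_id", "proc_code", "day"),
    "inpatient": ("patient_id", "admit_day", "discharge_day", "diagnoses"),
    "audiometry": ("patient_id", "exam_day") + AUDIO_COLS,
    "ha_orders": ("patient_id", "order_day", "user_type", "style", "laterality"),
    "battery_orders": ("patient_id", "order_day"),
    "ioi": ("patient_id", "completion_day", "entry_day") +
           tuple(f"item{i}" for i in range(1, 9)),
}

# columns holding integer days, rendered as ISO dates in CSV output
_DAY_COLS: dict[str, tuple[str, ...]] = {
    "demographics": ("record_day", "birth_day", "death_day"),
    "diagnoses_outpatient": ("day",),
    "procedures_outpatient": ("day",),
    "inpatient": ("admit_day", "discharge_day"),
    "audiometry": ("exam_day",),
    "ha_orders": ("order_day",),
    "battery_orders": ("order_day",),
    "ioi": ("completion_day", "entry_day"),
    "ground_truth": (),
}


def empty_table(name: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_SCHEMAS[name]})


@dataclasses.dataclass
class RawCohort:
    """The seven linked tables of one cohort, pre-cleaning."""

    demographics: pd.DataFrame
    diagnoses_outpatient: pd.DataFrame
    procedures_outpatient: pd.DataFrame
    inpatient: pd.DataFrame
    audiometry: pd.DataFrame
    ha_orders: pd.DataFrame
    battery_orders: pd.DataFrame
    ioi: pd.DataFrame

    def tables(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for name in TABLE_SCHEMAS:
            yield name, getattr(self, name)

    def copy(self) -> "RawCohort":
        return RawCohort(**{name: df.copy() for name, df in self.tables()})

    @property
    def n_patients(self) -> int:
        return self.demographics["patient_id"].nunique()

    def validate(self) -> None:
        """Check referential integrity: every id appears in demographics."""
        known = set(self.demographics["patient_id"])
        for name, df in self.tables():
            if name == "demographics" or df.empty:
                continue
            orphans = set(df["patient_id"]) - known
            if orphans:
                raise ValueError(
                    f"table {name!r} has patient ids absent from demographics: "
                    f"{sorted(orphans)[:5]}")


@dataclasses.dataclass
class GroundTruth:
    """Latent generator state retained for parameter-recovery testing.

    ``patients`` has one row per patient: true discontinuation day measured
    from the fitting day (``inf`` for never-discontinuers), fitting day,
    the set of truly chronic body systems (semicolon-joined), and its size.
    ``audiometry_true`` is the audiometry table before anomaly injection;
    ``anomaly_log`` records every injected anomaly.
    """

    patients: pd.DataFrame
    audiometry_true: pd.DataFrame
    anomaly_log: pd.DataFrame


def _to_iso(series: pd.Series) -> pd.Series:
    days = pd.to_numeric(series, errors="coerce")
    base = pd.Timestamp(EPOCH)
    out = (base + pd.to_timedelta(days, unit="D")).dt.strftime("%Y-%m-%d")
    return out.where(days.notna(), "")


def _from_iso(series: pd.Series) -> pd.Series:
    ts = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    days = (ts - pd.Timestamp(EPOCH)).dt.days
    return days.astype("Int64")


def write_cohort(cohort: RawCohort, out_dir: str | pathlib.Path,
                 fmt: str = "csv", ground_truth: GroundTruth | None = None,
                 manifest: dict | None = None) -> pathlib.Path:
    """Write one file per table plus optional ground-truth sidecar/manifest."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    items: list[tuple[str, pd.DataFrame]] = list(cohort.tables())
    if ground_truth is not None:
        items.append(("ground_truth", ground_truth.patients))
    for name, df in items:
        if fmt == "csv":
            rendered = df.copy()
            for col in _DAY_COLS.get(name, ()):
                if col in rendered.columns:
                    rendered[col] = _to_iso(rendered[col])
            rendered.to_csv(out / f"{name}.csv", index=False, lineterminator="\r\n")
        elif fmt == "parquet":
            df.to_parquet(out / f"{name}.parquet", index=False)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    if manifest is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True, default=str))
    return out


# columns restored to integers when a table is read back from CSV
_INT_COLS: dict[str, tuple[str, ...]] = {
    "demographics": ("patient_id", "station_id"),
    "diagnoses_outpatient": ("patient_id",),
    "procedures_outpatient": ("patient_id",),
    "inpatient": ("patient_id",),
    "audiometry": ("patient_id",),
    "ha_orders": ("patient_id",),
    "battery_orders": ("patient_id",),
    "ioi": ("patient_id",) + tuple(f"item{i}" for i in range(1, 9)),
}


def read_cohort(in_dir: str | pathlib.Path, fmt: str = "csv") -> RawCohort:
    src = pathlib.Path(in_dir)
    tables = {}
    for name in TABLE_SCHEMAS:
        path = src / f"{name}.{'parquet' if fmt == 'parquet' else 'csv'}"
        if not path.exists():
            raise FileNotFoundError(f"missing table {name!r}: {path}")
        if fmt == "csv":
            df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
            for col in _DAY_COLS.get(name, ()):
                df[col] = _from_iso(df[col])
            for col in _INT_COLS.get(name, ()):
                df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
        else:
            df = pd.read_parquet(path)
        tables[name] = df
    return RawCohort(**tables)


def first_ha_orders(ha_orders: pd.DataFrame) -> pd.DataFrame:
    """One row per patient: the earliest HA order (the index order)."""
    if ha_orders.empty:
        return ha_orders.copy()
    idx = ha_orders.groupby("patient_id")["order_day"].idxmin()
    return ha_orders.loc[idx].reset_index(drop=True)
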