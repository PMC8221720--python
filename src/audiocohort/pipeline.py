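"""End-to-end pipeline: cleaning, linkage, derived measures, summaries.

Stage order: demographics merge -> audiogram cleaning/PTA -> fitting-date
assignment -> persistence -> IOI-HA scoring -> multimorbidity -> stratified
summaries.  Every stage reports inclusion/exclusion counts so that
included + excluded always reconciles with the stage input.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import audiometry as am
from . import care_pathway as cp
from . import demographics as dg
from . import ioi as ioi_mod
from . import morbidity as mb
from .cohort import RawCohort, first_ha_orders, read_cohort
from .config import PipelineConfig
from .persistence import PersistenceParams, persistence_flags

log = logging.getLogger("audiocohort")


@dataclasses.dataclass
class ReportBundle:
    """All pipeline outputs: per-analysis tables, summary, exclusion log."""
    patients: pd.DataFrame          # one row per patient with derived columns
    pta_summary: pd.DataFrame
    fittings: pd.DataFrame
    ioi_results: pd.DataFrame
    stage_log: pd.DataFrame         # stage, included, excluded, reason counts
    cleaning_log: dict
    summary: dict

    def write(self, out_dir: str | pathlib.Path, fmt: str = "csv") -> pathlib.Path:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {"patients": self.patients, "pta_summary": self.pta_summary,
                  "fittings": self.fittings, "ioi_results": self.ioi_results,
                  "stage_log": self.stage_log}
        for name, df in tables.items():
            if fmt == "parquet":
                df.to_parquet(out / f"{name}.parquet", index=False)
            else:
                df.to_csv(out / f"{name}.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(self.summary, indent=2, sort_keys=True, default=_json_default))
        return out


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _age_band(ages: pd.Series, edges: Sequence[int]) -> pd.Series:
    bins = [-np.inf] + list(edges) + [np.inf]
    labels = [f"<{edges[0]}"] + \
        [f"{a}-{b - 1}" for a, b in zip(edges, edges[1:])] + [f"{edges[-1]}+"]
    return pd.cut(ages, bins=bins, labels=labels, right=False).astype(str)


def run_pipeline(cohort: RawCohort | str | pathlib.Path,
                 config: Optional[PipelineConfig] = None) -> ReportBundle:
    """Run every stage on a cohort (in memory or a table directory)."""
    config = config or PipelineConfig()
    logging.basicConfig(level=config.log_level)
    if not isinstance(cohort, RawCohort):
        cohort = read_cohort(cohort, fmt=config.table_format)
    cohort.validate()
    params = PersistenceParams(dose_days=config.dose_days,
                               gap_days=config.gap_days,
                               eval_days=config.eval_days)
    stage_rows = []

    # --- demographics -------------------------------------------------------
    merged = dg.merge_demographics_table(cohort.demographics)
    first_orders = first_ha_orders(cohort.ha_orders)
    first_order_days = (first_orders.set_index("patient_id")["order_day"]
                        if not first_orders.empty else pd.Series(dtype=float))
    merged = dg.flag_implausible_table(merged, first_order_days)
    n_pat = len(merged)
    stage_rows.append({"stage": "demographics", "n_in": n_pat, "n_out": n_pat,
                       "n_inconsistent": int(merged["inconsistent"].sum()),
                       "n_implausible": int(merged["implausible"].sum())})

    # --- audiometry ---------------------------------------------------------
    clean_audio, cleaning_log = am.clean_audiometry_table(cohort.audiometry)
    pta = am.pta_summary_table(clean_audio)
    stage_rows.append({"stage": "audiometry", "n_in": len(cohort.audiometry),
                       "n_out": len(pta),
                       "n_ceiling_substituted": cleaning_log[am.CEILING_SUBSTITUTED],
                       "n_set_missing": cleaning_log[am.SET_MISSING]})

    # --- care pathway -------------------------------------------------------
    fittings = cp.fitting_table(cohort.ha_orders, cohort.battery_orders,
                                max_lag=config.fitting_max_lag)
    n_fit = int(fittings["fitting_day"].notna().sum()) if len(fittings) else 0
    stage_rows.append({"stage": "fitting_assignment", "n_in": len(fittings),
                       "n_out": n_fit,
                       "n_no_fitting": len(fittings) - n_fit})

    # --- persistence --------------------------------------------------------
    if config.single_order_only and not cohort.ha_orders.empty:
        order_counts = cohort.ha_orders.groupby("patient_id").size()
        single = set(order_counts.index[order_counts == 1])
        fit_for_pers = fittings[fittings["patient_id"].isin(single)]
    else:
        fit_for_pers = fittings
    flags = persistence_flags(fit_for_pers, cohort.battery_orders, params)
    patients = merged.merge(
        fittings[["patient_id", "ha_order_day", "fitting_day", "lag"]],
        on="patient_id", how="left")
    patients["persistent"] = patients["patient_id"].map(flags)
    death = patients["death_day"]
    patients["survived_eval"] = (patients["fitting_day"].notna() &
                                 (death.isna() |
                                  (death >= patients["fitting_day"] +
                                   params.eval_days)))
    included = (patients["persistent"].notna() & patients["survived_eval"] &
                ~patients["implausible"])
    patients["persistence_included"] = included
    n_death_excl = int((patients["persistent"].notna() &
                        ~patients["survived_eval"] &
                        ~patients["implausible"]).sum())
    stage_rows.append({
        "stage": "persistence", "n_in": int(patients["persistent"].notna().sum()),
        "n_out": int(included.sum()), "n_excluded_death": n_death_excl,
        "n_excluded_implausible": int((patients["persistent"].notna() &
                                       patients["implausible"]).sum())})

    # --- IOI ----------------------------------------------------------------
    ioi_results = ioi_mod.score_ioi_table(
        cohort.ioi, cohort.ha_orders, fittings,
        min_days=config.ioi_min_days, max_days=config.ioi_max_days)
    stage_rows.append({"stage": "ioi", "n_in": len(cohort.ioi),
                       "n_out": int(ioi_results["included"].sum())
                       if len(ioi_results) else 0})

    # --- morbidity ----------------------------------------------------------
    mm = mb.multimorbidity_table(
        cohort.diagnoses_outpatient, first_order_days, mb.load_cci_map(),
        window_days=config.morbidity_window_days,
        min_codes=config.morbidity_min_codes,
        exclude_prefix=config.morbidity_exclude_prefix)
    cond = mb.condition_flags_table(cohort.diagnoses_outpatient,
                                    first_order_days,
                                    mb.default_condition_definitions())
    inpt = mb.inpatient_flags_table(cohort.inpatient, first_order_days)
    stage_rows.append({"stage": "morbidity", "n_in": n_pat, "n_out": len(mm)})

    # --- assemble patient-level frame --------------------------------------
    patients = (patients.merge(mm, on="patient_id", how="left")
                .merge(cond, on="patient_id", how="left")
                .merge(inpt, on="patient_id", how="left")
                .merge(pta, on="patient_id", how="left"))
    patients["user_type"] = patients["patient_id"].map(
        first_orders.set_index("patient_id")["user_type"]
        if not first_orders.empty else pd.Series(dtype=object))
    order_day = patients["patient_id"].map(first_order_days)
    patients["age_at_order"] = (order_day - patients["birth_day"]) / 365.25
    patients["age_band"] = _age_band(patients["age_at_order"],
                                     config.age_band_edges)
    ioi_included = (ioi_results[ioi_results["included"]]
                    if len(ioi_results) else ioi_results)
    if len(ioi_included):
        patients["ioi_total"] = patients["patient_id"].map(
            ioi_included.groupby("patient_id")["total"].mean())
    else:
        patients["ioi_total"] = np.nan

    stage_log = pd.DataFrame(stage_rows)
    summary = summarize_cohort(patients, cohort, ioi_results)
    bundle = ReportBundle(patients=patients, pta_summary=pta,
                          fittings=fittings, ioi_results=ioi_results,
                          stage_log=stage_log, cleaning_log=cleaning_log,
                          summary=summary)
    if config.output_dir:
        bundle.write(config.output_dir, fmt=config.table_format)
    return bundle


def _stats(series: pd.Series) -> dict:
    s = pd.to_numeric(series, errors="coerce").dropna()
    if s.empty:
        return {"n": 0}
    return {"n": int(s.size), "mean": float(s.mean()),
            "sd": float(s.std(ddof=1)) if s.size > 1 else 0.0,
            "median": float(s.median())}


def summarize_cohort(patients: pd.DataFrame, cohort: RawCohort,
                     ioi_results: pd.DataFrame) -> dict:
    """Descriptive summary: demographics, orders, PTA, persistence, IOI."""
    out: dict = {"n_patients": len(patients)}
    if patients.empty:
        return out | {"male_fraction": None, "persistence": None}
    out["male_fraction"] = float((patients["gender"] == "M").mean())
    out["age_by_user_type"] = {
        str(ut): _stats(g["age_at_order"])
        for ut, g in patients.groupby("user_type", dropna=False)}
    if not cohort.ha_orders.empty:
        n_orders = cohort.ha_orders.groupby("patient_id").size()
        out["ha_orders_per_patient"] = _stats(n_orders)
        out["style_fractions"] = (cohort.ha_orders["style"]
                                  .value_counts(normalize=True).to_dict())
        out["laterality_fractions"] = (cohort.ha_orders["laterality"]
                                       .value_counts(normalize=True).to_dict())
    if not cohort.battery_orders.empty:
        n_bat = cohort.battery_orders.groupby("patient_id").size()
        out["battery_orders_per_patient"] = _stats(n_bat)
        gaps = (cohort.battery_orders.sort_values(["patient_id", "order_day"])
                .groupby("patient_id")["order_day"].diff().dropna())
        out["inter_order_gap_days"] = _stats(gaps)
    out["order_to_first_battery_days"] = _stats(patients["lag"])
    out["pta"] = {"left": _stats(patients["pta_left"]),
                  "right": _stats(patients["pta_right"]),
                  "bilateral": _stats(patients["pta_bilateral"])}
    with_pta = patients["pta_left"].notna()
    out["asymmetry_fraction"] = (
        float(patients.loc[with_pta, "asymmetric"].mean())
        if with_pta.any() else None)
    inc = patients["persistence_included"]
    out["persistence"] = {
        "proportion": float(patients.loc[inc, "persistent"].mean())
        if inc.any() else None,
        "n_included": int(inc.sum()),
        "n_excluded_death": int((patients["persistent"].notna() & ~inc).sum()),
    }
    out["multimorbidity"] = _stats(patients["mm_index"])
    if len(ioi_results):
        inc_ioi = ioi_results[ioi_results["included"]]
        out["ioi"] = {"n_surveys": len(ioi_results),
                      "n_included": len(inc_ioi),
                      "total": _stats(inc_ioi["total"])}
    return out


def stratified_persistence(patients: pd.DataFrame, strata: Sequence[str],
                           min_stratum_n: int = 200) -> pd.DataFrame:
    """Mean persistence within each cross-stratum; small strata suppressed.

    Only patients passing the persistence inclusion filter contribute.
    Strata with fewer than ``min_stratum_n`` patients are dropped, matching
    the reporting floor used for subgroup displays.
    """
    for var in strata:
        if var not in patients.columns:
            raise KeyError(f"unknown stratifier {var!r}")
    inc = patients[patients["persistence_included"].fillna(False)]
    if inc.empty:
        return pd.DataFrame(columns=list(strata) + ["n", "persistence"])
    grouped = inc.groupby(list(strata), dropna=False, observed=True)
    rows = []
    for key, g in grouped:
        key = key if isinstance(key, tuple) else (key,)
        if len(g) < min_stratum_n:
            continue
        rows.append(dict(zip(strata, key)) |
                    {"n": len(g), "persistence": float(g["persistent"].mean())})
    return pd.DataFrame(rows, columns=list(strata) + ["n", "persistence"])
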