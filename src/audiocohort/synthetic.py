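"""Synthetic VA-style hearing-aid cohort generator.

Produces the seven linked tables of a :class:`~audiocohort.cohort.RawCohort`
with the statistical structure the downstream analysis assumes, together
with the latent ground truth (true discontinuation times, true chronic
body-system sets, pre-anomaly thresholds) needed for parameter-recovery
testing.  All dates are integer days from the cohort epoch; hearing-aid
orders fall uniformly in a 31-month order window and post-order streams run
to an observation horizon about 69 months after the window opens.

The data-generating process, per patient:

* demographics — gender and a two-component normal age mixture; one
  demographic record per station (a subset of patients attend multiple
  stations, with duplicate records that agree unless an inconsistency
  anomaly is injected); death follows an age-banded exponential hazard.
* audiometry — sloping bilateral sensorineural-style losses with a
  patient-level severity effect, an ear asymmetry mixture with a left-worse
  excess, and interoctave frequencies only partially tested.
* battery orders — a first order lags the HA order by a truncated-normal
  delay; later orders recur with log-normal gaps (median near the 6-month
  supply period) truncated below the dose-plus-acceptable-gap horizon, and
  stop at the true discontinuation time, death, or the horizon.
* discontinuation — a point mass of never-discontinuers plus an
  exponential hazard, optionally coupled to chronic-condition burden.
* diagnoses — chronic ICD-9 codes per affected body system inside and
  outside the 12-month pre-order window, hearing-loss codes (389.XX) for
  everyone, and non-chronic noise codes.
* IOI-HA — about one fifth of fitted patients return a complete survey,
  mostly inside the 14-180-day window; item 8 tracks true hearing loss.

Anomaly injection happens after clean generation, so the ground truth
always holds pre-anomaly values and the injection log can be reconciled
exactly against the pipeline's cleaning/exclusion log.
"""

from __future__ import annotations

import dataclasses
import functools
import math
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import (AUDIO_COLS, AUDIO_FREQS, GroundTruth, RawCohort,
                     empty_table)
from .config import KNOWN_ANOMALIES, CohortConfig
from .units import DAYS_PER_YEAR

STYLES = ("BTE", "ITE", "RIC")
STYLE_P = (0.264, 0.300, 0.436)
LATERALITIES = ("both", "left", "right")
LATERALITY_P = (0.910, 0.049, 0.041)

#: mean threshold shape (dB HL) of a sloping high-frequency loss
BASE_SHAPE = {250: 25.0, 500: 30.0, 1000: 37.0, 1500: 43.0, 2000: 50.0,
              3000: 57.0, 4000: 62.0, 6000: 66.0, 8000: 70.0}
INTEROCTAVE = (1500, 3000, 6000)
INTEROCTAVE_TESTED_P = 0.7

#: IOI item response distribution for items 1-7 (skewed high, mean ~4.1)
ITEM_P = (0.02, 0.05, 0.15, 0.38, 0.40)

_BASE_4F = float(np.mean([BASE_SHAPE[f] for f in (500, 1000, 2000, 4000)]))
_ASYM_OFFSET_RANGE = (15.0, 30.0)

PROC_AUDIOMETRY = "92557"
PROC_ORDER_EVAL = "92626"
PROC_FITTING = "V5011"
PROC_FOLLOWUP = "92593"
HEARING_LOSS_CODES = ("389.10", "389.15", "389.18")


@functools.lru_cache(maxsize=1)
def _code_pools() -> tuple[dict[int, tuple[str, ...]], tuple[str, ...]]:
    """(chronic codes per body system excluding 389.XX, non-chronic codes)."""
    path = resources.files("audiocohort.data") / "cci_map_toy.csv"
    df = pd.read_csv(str(path), dtype={"code": str})
    chronic: dict[int, list[str]] = {}
    nonchronic: list[str] = []
    for code, flag, system in df.itertuples(index=False):
        if str(code).startswith("389"):
            continue
        if int(flag):
            chronic.setdefault(int(system), []).append(code)
        else:
            nonchronic.append(code)
    return ({s: tuple(v) for s, v in chronic.items()}, tuple(nonchronic))


def _sample_gaps(rng: np.random.Generator, cfg: CohortConfig,
                 size: int) -> np.ndarray:
    g = cfg.inter_battery_gap
    raw = rng.lognormal(math.log(g.median_days), g.log_sd, size)
    return np.clip(np.rint(raw), g.min_days, g.max_days).astype(np.int64)


def _sample_discontinuation(rng: np.random.Generator, cfg: CohortConfig,
                            n_systems: np.ndarray) -> np.ndarray:
    """True discontinuation day relative to fitting (inf = never)."""
    d = cfg.discontinuation
    never = rng.random(len(n_systems)) < d.never_fraction
    mean_k = sum(cfg.chronic_prevalence.by_system.values())
    hazard = d.hazard_per_year * np.exp(
        d.morbidity_coupling * (n_systems - mean_k))
    tau_days = rng.exponential(1.0, len(n_systems)) / hazard * DAYS_PER_YEAR
    return np.where(never, np.inf, tau_days)


def _death_rates(cfg: CohortConfig, ages: np.ndarray) -> np.ndarray:
    bands = sorted(cfg.death_hazard.items())
    rates = np.full(len(ages), bands[0][1], dtype=float)
    for edge, rate in bands:
        rates[ages >= edge] = rate
    return rates


def generate_cohort(config: CohortConfig) -> tuple[RawCohort, GroundTruth]:
    """Generate one cohort plus its latent ground truth.

    Identical ``config`` (including ``seed``) reproduces byte-identical
    tables.  Battery orders exist only while the patient is alive and
    strictly before the true discontinuation day; anomalies are injected
    last, at the rates in ``config.anomaly_rates``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        empty = RawCohort(**{name: empty_table(name) for name in (
            "demographics", "diagnoses_outpatient", "procedures_outpatient",
            "inpatient", "audiometry", "ha_orders", "battery_orders", "ioi")})
        gt = GroundTruth(patients=pd.DataFrame(columns=[
            "patient_id", "fitting_day", "discontinuation_day",
            "n_chronic_systems", "chronic_systems",
            "pta_true_left", "pta_true_right"]),
            audiometry_true=empty_table("audiometry"),
            anomaly_log=pd.DataFrame(columns=["anomaly", "patient_id",
                                              "table", "column", "detail"]))
        return empty, gt

    pid = np.arange(1, n + 1, dtype=np.int64)

    # -- demographics core -------------------------------------------------
    male = rng.random(n) < config.male_fraction
    gender = np.where(male, "M", "F")
    weights = np.array([c.weight for c in config.age_mixture])
    comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
    means = np.array([c.mean for c in config.age_mixture])
    sds = np.array([c.sd for c in config.age_mixture])
    ages = np.clip(rng.normal(means[comp], sds[comp]), 20.0, 100.0)
    order_day = rng.integers(0, config.order_window_days + 1, n)
    birth_day = order_day - np.rint(ages * DAYS_PER_YEAR).astype(np.int64)

    # -- HA orders ----------------------------------------------------------
    p2, p3 = config.extra_order_probs
    u_orders = rng.random(n)
    n_orders = np.where(u_orders < p3, 3, np.where(u_orders < p2 + p3, 2, 1))
    first_new = rng.random(n) < config.new_user_fraction
    ha_rows = {"patient_id": [pid], "order_day": [order_day],
               "user_type": [np.where(first_new, "new", "experienced")]}
    style = rng.choice(STYLES, size=n, p=np.array(STYLE_P) / sum(STYLE_P))
    lat = rng.choice(LATERALITIES, size=n,
                     p=np.array(LATERALITY_P) / sum(LATERALITY_P))
    ha_rows["style"], ha_rows["laterality"] = [style], [lat]
    for extra in (2, 3):
        mask = n_orders >= extra
        m = int(mask.sum())
        later = order_day[mask] + rng.integers(60, 701, m)
        later = np.minimum(later, config.order_window_days)
        ha_rows["patient_id"].append(pid[mask])
        ha_rows["order_day"].append(later)
        ha_rows["user_type"].append(np.full(m, "experienced"))
        ha_rows["style"].append(rng.choice(STYLES, size=m,
                                           p=np.array(STYLE_P) / sum(STYLE_P)))
        ha_rows["laterality"].append(
            rng.choice(LATERALITIES, size=m,
                       p=np.array(LATERALITY_P) / sum(LATERALITY_P)))
    ha_orders = pd.DataFrame({k: np.concatenate(v) for k, v in ha_rows.items()})
    ha_orders = ha_orders.sort_values(["patient_id", "order_day"],
                                      kind="stable").reset_index(drop=True)

    # -- death --------------------------------------------------------------
    rates = _death_rates(config, ages)
    with np.errstate(divide="ignore"):
        t_death = rng.exponential(1.0, n) / np.where(rates > 0, rates, np.inf)
    death_day = order_day + np.rint(t_death * DAYS_PER_YEAR)
    death_day = np.where(death_day <= config.horizon_days, death_day, np.nan)

    # -- chronic conditions and discontinuation -----------------------------
    systems = sorted(config.chronic_prevalence.by_system)
    prev = np.array([config.chronic_prevalence.by_system[s] for s in systems])
    present = rng.random((n, len(systems))) < prev
    n_sys = present.sum(axis=1)
    tau_rel = _sample_discontinuation(rng, config, n_sys)

    # -- battery orders ------------------------------------------------------
    otb = config.order_to_first_battery
    delay = np.rint(np.clip(rng.normal(otb.mean_days, otb.sd_days, n),
                            0, None)).astype(np.int64)
    fitting_day = order_day + delay
    has_batt = rng.random(n) >= config.no_battery_prob
    alive_at_fit = np.isnan(death_day) | (fitting_day < death_day)
    has_batt &= alive_at_fit & (fitting_day <= config.horizon_days)
    death_rel = np.where(np.isnan(death_day), np.inf, death_day - fitting_day)
    horizon_rel = config.horizon_days - fitting_day

    bat_pids = [pid[has_batt]]
    bat_days = [fitting_day[has_batt]]
    t_rel = np.zeros(n, dtype=np.int64)
    active = has_batt.copy()
    guard = int(config.horizon_days / config.inter_battery_gap.min_days) + 5
    for _ in range(guard):
        if not active.any():
            break
        gaps = _sample_gaps(rng, config, n)
        t_next = t_rel + gaps
        # an order occurs only strictly before discontinuation/death and
        # within the observation horizon
        ok = active & (t_next < np.minimum(tau_rel, death_rel)) & \
            (t_next <= horizon_rel)
        bat_pids.append(pid[ok])
        bat_days.append(fitting_day[ok] + t_next[ok])
        t_rel = np.where(ok, t_next, t_rel)
        active = ok
    battery_orders = pd.DataFrame({
        "patient_id": np.concatenate(bat_pids),
        "order_day": np.concatenate(bat_days).astype(np.int64)})
    battery_orders = battery_orders.sort_values(
        ["patient_id", "order_day"], kind="stable").reset_index(drop=True)

    # -- audiometry ----------------------------------------------------------
    has_audio = rng.random(n) < config.audiogram_available_prob
    u_lag = rng.random(n)
    exam_lag = np.select(
        [u_lag < 0.67, u_lag < 0.81, u_lag < 0.97],
        [0, rng.integers(1, 15, n), rng.integers(15, 184, n)],
        default=rng.integers(184, 366, n))
    exam_day = order_day - exam_lag

    freqs = np.array(AUDIO_FREQS, dtype=float)
    shape = np.array([BASE_SHAPE[f] for f in AUDIO_FREQS])
    severity = rng.normal(0.0, 16.4, n)
    eps_l = rng.normal(0.0, 6.0, (n, len(freqs)))
    eps_r = rng.normal(0.0, 6.0, (n, len(freqs)))
    asym = rng.random(n) < config.asymmetry_prob
    left_worse = rng.random(n) < config.left_worse_prob_given_asym
    offset = rng.uniform(*_ASYM_OFFSET_RANGE, n)
    asym_l = np.where(asym & left_worse, offset, 0.0)
    asym_r = np.where(asym & ~left_worse, offset, 0.0)
    mean_off = np.mean(_ASYM_OFFSET_RANGE)
    exp_asym_l = config.asymmetry_prob * config.left_worse_prob_given_asym * mean_off
    exp_asym_r = config.asymmetry_prob * (1 - config.left_worse_prob_given_asym) * mean_off
    shift_l = config.pta_mean_left - _BASE_4F - exp_asym_l
    shift_r = config.pta_mean_right - _BASE_4F - exp_asym_r
    thr_l = shape[None, :] + (severity + shift_l + asym_l)[:, None] + eps_l
    thr_r = shape[None, :] + (severity + shift_r + asym_r)[:, None] + eps_r
    thr_l = np.clip(np.round(thr_l / 5.0) * 5.0, 0, 110).astype(np.int64)
    thr_r = np.clip(np.round(thr_r / 5.0) * 5.0, 0, 110).astype(np.int64)
    pta_idx = np.array([AUDIO_FREQS.index(f) for f in (500, 1000, 2000, 4000)])
    pta_true_l = thr_l[:, pta_idx].mean(axis=1)
    pta_true_r = thr_r[:, pta_idx].mean(axis=1)

    second = has_audio & (rng.random(n) < config.multiple_audiogram_prob)
    exam2_day = exam_day + rng.integers(30, 301, n)
    thr2_l = np.clip(np.round((thr_l + rng.normal(0, 4, thr_l.shape)) / 5.0)
                     * 5.0, 0, 110).astype(np.int64)
    thr2_r = np.clip(np.round((thr_r + rng.normal(0, 4, thr_r.shape)) / 5.0)
                     * 5.0, 0, 110).astype(np.int64)
    inter_mask1 = rng.random((n, len(freqs))) < INTEROCTAVE_TESTED_P
    inter_mask2 = rng.random((n, len(freqs))) < INTEROCTAVE_TESTED_P

    def _audio_frame(mask, exam, tl, tr, tested):
        rows = {"patient_id": pid[mask], "exam_day": exam[mask]}
        for ei, (prefix, thr) in enumerate((("l", tl), ("r", tr))):
            for fi, f in enumerate(AUDIO_FREQS):
                col = np.char.mod("%d", thr[mask, fi])
                if f in INTEROCTAVE:
                    col = np.where(tested[mask, fi], col, "")
                rows[f"{prefix}{f}"] = col
        return pd.DataFrame(rows)

    audiometry = pd.concat([
        _audio_frame(has_audio, exam_day, thr_l, thr_r, inter_mask1),
        _audio_frame(second, exam2_day, thr2_l, thr2_r, inter_mask2),
    ], ignore_index=True).sort_values(
        ["patient_id", "exam_day"], kind="stable").reset_index(drop=True)

    # -- IOI-HA ---------------------------------------------------------------
    resp = has_batt & (rng.random(n) < config.ioi_response_prob)
    u_band = rng.random(n)
    band_p = np.array([0.03, 0.157, 0.540, 0.259, 0.045])
    band_p = np.concatenate([band_p[:1], band_p[1:] / band_p[1:].sum() * 0.95])
    edges = np.cumsum(np.append(band_p, 0.02))
    lag_draws = np.stack([rng.integers(0, 14, n), rng.integers(14, 31, n),
                          rng.integers(31, 61, n), rng.integers(61, 121, n),
                          rng.integers(121, 181, n),
                          rng.integers(181, 366, n)])
    band = np.searchsorted(edges, u_band)
    band = np.clip(band, 0, 5)
    ioi_lag = lag_draws[band, np.arange(n)]
    completion = fitting_day + ioi_lag
    entry = completion + rng.poisson(3.0, n)
    items = rng.choice(np.arange(1, 6), size=(n, 7),
                       p=np.array(ITEM_P) / sum(ITEM_P))
    item8_raw = np.rint(1.0 + (np.where(has_audio, (pta_true_l + pta_true_r) / 2,
                                        45.0) - 20.0) / 18.0
                        + rng.normal(0, 0.9, n))
    item8 = np.clip(item8_raw, 1, 5).astype(np.int64)
    dup = resp & (rng.random(n) < config.duplicate_survey_prob)
    dup_completion = fitting_day + rng.integers(14, 181, n)
    dup_items = rng.choice(np.arange(1, 6), size=(n, 7),
                           p=np.array(ITEM_P) / sum(ITEM_P))

    def _ioi_frame(mask, comp, ent, it, it8):
        rows = {"patient_id": pid[mask], "completion_day": comp[mask],
                "entry_day": ent[mask]}
        for i in range(7):
            rows[f"item{i + 1}"] = it[mask, i]
        rows["item8"] = it8[mask]
        return pd.DataFrame(rows)

    ioi = pd.concat([
        _ioi_frame(resp, completion, entry, items, item8),
        _ioi_frame(dup, dup_completion, dup_completion + 2, dup_items, item8),
    ], ignore_index=True).sort_values(
        ["patient_id", "completion_day"], kind="stable").reset_index(drop=True)

    # -- diagnoses ------------------------------------------------------------
    pools, nonchronic_pool = _code_pools()
    cp = config.chronic_prevalence
    diag_pids, diag_codes, diag_days = [], [], []

    pi, si = np.nonzero(present)
    sys_ids = np.array(systems)[si]
    for label, count_arr, day_lo, day_hi in (
            ("win", 1 + rng.poisson(cp.extra_codes_mean, len(pi)), 1, 366),
            ("out", rng.poisson(cp.out_of_window_mean, len(pi)), 366, 1096)):
        rep_p = np.repeat(pi, count_arr)
        rep_s = np.repeat(sys_ids, count_arr)
        back = rng.integers(day_lo, day_hi, len(rep_p))
        days = order_day[rep_p] - back
        codes = np.empty(len(rep_p), dtype=object)
        for s in np.unique(rep_s):
            pool = pools.get(int(s))
            if not pool:
                continue
            m = rep_s == s
            codes[m] = np.array(pool, dtype=object)[
                rng.integers(0, len(pool), int(m.sum()))]
        keep = codes != None  # noqa: E711  (systems without a pool)
        diag_pids.append(pid[rep_p[keep]])
        diag_codes.append(codes[keep])
        diag_days.append(days[keep])

    n_noise = rng.poisson(cp.noise_codes_mean, n)
    rep = np.repeat(np.arange(n), n_noise)
    noise_codes = np.array(nonchronic_pool, dtype=object)[
        rng.integers(0, len(nonchronic_pool), len(rep))]
    noise_days = order_day[rep] + rng.integers(-1095, 366, len(rep))
    diag_pids.append(pid[rep])
    diag_codes.append(noise_codes)
    diag_days.append(noise_days)

    n_hear = 1 + rng.poisson(1.0, n)
    rep = np.repeat(np.arange(n), n_hear)
    hear_codes = np.array(HEARING_LOSS_CODES, dtype=object)[
        rng.integers(0, len(HEARING_LOSS_CODES), len(rep))]
    hear_days = order_day[rep] + rng.integers(-365, 31, len(rep))
    diag_pids.append(pid[rep])
    diag_codes.append(hear_codes)
    diag_days.append(hear_days)

    diagnoses = pd.DataFrame({
        "patient_id": np.concatenate(diag_pids),
        "icd_code": np.concatenate(diag_codes),
        "day": np.concatenate(diag_days).astype(np.int64)})
    diagnoses = diagnoses.sort_values(["patient_id", "day", "icd_code"],
                                      kind="stable").reset_index(drop=True)

    # -- procedures -----------------------------------------------------------
    proc_pids = [pid, pid[has_audio], pid[second], pid[has_batt]]
    proc_codes = [np.full(n, PROC_ORDER_EVAL),
                  np.full(int(has_audio.sum()), PROC_AUDIOMETRY),
                  np.full(int(second.sum()), PROC_AUDIOMETRY),
                  np.full(int(has_batt.sum()), PROC_FITTING)]
    proc_days = [order_day, exam_day[has_audio], exam2_day[second],
                 fitting_day[has_batt]]
    n_fup = rng.poisson(1.2, n)
    rep = np.repeat(np.arange(n), n_fup)
    fup_days = fitting_day[rep] + rng.integers(14, 901, len(rep))
    keep = fup_days <= config.horizon_days
    proc_pids.append(pid[rep[keep]])
    proc_codes.append(np.full(int(keep.sum()), PROC_FOLLOWUP))
    proc_days.append(fup_days[keep])
    procedures = pd.DataFrame({
        "patient_id": np.concatenate(proc_pids),
        "proc_code": np.concatenate(proc_codes),
        "day": np.concatenate(proc_days).astype(np.int64)})
    procedures = procedures.sort_values(["patient_id", "day", "proc_code"],
                                        kind="stable").reset_index(drop=True)

    # -- inpatient ------------------------------------------------------------
    has_inpt = rng.random(n) < config.inpatient_prob
    n_stay = np.where(has_inpt, 1 + rng.poisson(0.4, n), 0)
    rep = np.repeat(np.arange(n), n_stay)
    admit = order_day[rep] + rng.integers(-1095, 500, len(rep))
    los = 1 + rng.poisson(4.0, len(rep))
    stay_codes = np.array(nonchronic_pool + HEARING_LOSS_CODES, dtype=object)
    diag_str = stay_codes[rng.integers(0, len(stay_codes), len(rep))]
    inpatient = pd.DataFrame({
        "patient_id": pid[rep], "admit_day": admit,
        "discharge_day": admit + los, "diagnoses": diag_str})
    inpatient = inpatient.sort_values(["patient_id", "admit_day"],
                                      kind="stable").reset_index(drop=True)

    # -- demographics records ---------------------------------------------------
    u_multi = rng.random(n)
    extra_third = rng.random(n) < 0.2
    n_rec = 1 + (u_multi < config.multi_station_prob).astype(int)
    n_rec += ((u_multi < config.multi_station_prob) & extra_third).astype(int)
    rep = np.repeat(np.arange(n), n_rec)
    stations = rng.integers(1, 500, len(rep))
    record_days = rng.integers(-1800, 1, len(rep))
    demographics = pd.DataFrame({
        "patient_id": pid[rep],
        "station_id": stations,
        "record_day": record_days,
        "birth_day": birth_day[rep],
        "death_day": death_day[rep],
        "gender": gender[rep]})
    demographics = demographics.sort_values(
        ["patient_id", "record_day", "station_id"],
        kind="stable").reset_index(drop=True)

    cohort = RawCohort(
        demographics=demographics, diagnoses_outpatient=diagnoses,
        procedures_outpatient=procedures, inpatient=inpatient,
        audiometry=audiometry, ha_orders=ha_orders,
        battery_orders=battery_orders, ioi=ioi)

    chronic_strs = [";".join(str(s) for s, p in zip(systems, row) if p)
                    for row in present]
    gt_patients = pd.DataFrame({
        "patient_id": pid,
        "fitting_day": np.where(has_batt, fitting_day, np.nan),
        "discontinuation_day": tau_rel,
        "n_chronic_systems": n_sys,
        "chronic_systems": chronic_strs,
        "pta_true_left": np.where(has_audio, pta_true_l, np.nan),
        "pta_true_right": np.where(has_audio, pta_true_r, np.nan)})

    cohort, log = inject_anomalies(cohort, config.anomaly_rates,
                                   seed=config.seed + 1)
    ground_truth = GroundTruth(patients=gt_patients,
                               audiometry_true=audiometry,
                               anomaly_log=log)
    return cohort, ground_truth


def inject_anomalies(cohort: RawCohort, rates: dict[str, float],
                     seed: int) -> tuple[RawCohort, pd.DataFrame]:
    """Apply data-entry anomalies at the given per-unit rates.

    Anomalies and their units:

    * ``above_limit_code`` — per non-empty audiometric entry: replace with
      the above-limit token ``NR``.
    * ``ambiguous_nonnumeric`` — per entry: replace with ``CNT``.
    * ``not_divisible_by_5`` — per entry: nudge the value by +2 dB.
    * ``duplicate_demographic_inconsistency`` — per patient with multiple
      demographic records: flip the gender of the latest-dated record.
    * ``implausible_death_date`` — per patient: set the death date 100 days
      before the first HA order.

    The three audiometric anomalies are mutually exclusive per entry.
    Returns the modified cohort and a log with one row per injection.
    """
    unknown = set(rates) - KNOWN_ANOMALIES
    if unknown:
        raise ValueError(f"unknown anomaly keys: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    log_rows: list[dict] = []

    r_above = rates.get("above_limit_code", 0.0)
    r_ambig = rates.get("ambiguous_nonnumeric", 0.0)
    r_nd5 = rates.get("not_divisible_by_5", 0.0)
    audio = out.audiometry
    if len(audio) and (r_above or r_ambig or r_nd5):
        for col in AUDIO_COLS:
            vals = audio[col].astype(str).to_numpy(dtype=object)
            eligible = vals != ""
            u = rng.random(len(vals))
            pick_above = eligible & (u < r_above)
            pick_ambig = eligible & (u >= r_above) & (u < r_above + r_ambig)
            pick_nd5 = eligible & (u >= r_above + r_ambig) & \
                (u < r_above + r_ambig + r_nd5)
            vals[pick_above] = "NR"
            vals[pick_ambig] = "CNT"
            if pick_nd5.any():
                idx = np.nonzero(pick_nd5)[0]
                vals[idx] = [str(int(float(v)) + 2) for v in vals[idx]]
            audio[col] = vals
            for anomaly, mask in (("above_limit_code", pick_above),
                                  ("ambiguous_nonnumeric", pick_ambig),
                                  ("not_divisible_by_5", pick_nd5)):
                for i in np.nonzero(mask)[0]:
                    log_rows.append({
                        "anomaly": anomaly,
                        "patient_id": int(audio["patient_id"].iloc[i]),
                        "table": "audiometry", "column": col,
                        "detail": f"exam_day={int(audio['exam_day'].iloc[i])}"})

    r_dup = rates.get("duplicate_demographic_inconsistency", 0.0)
    demo = out.demographics
    if len(demo) and r_dup:
        counts = demo.groupby("patient_id")["patient_id"].transform("size")
        multi_ids = np.array(sorted(set(demo.loc[counts > 1, "patient_id"])))
        chosen = multi_ids[rng.random(len(multi_ids)) < r_dup]
        for p in chosen:
            rows = demo.index[demo["patient_id"] == p]
            target = demo.loc[rows, "record_day"].astype(float).idxmax()
            old = demo.at[target, "gender"]
            demo.at[target, "gender"] = "F" if old == "M" else "M"
            log_rows.append({"anomaly": "duplicate_demographic_inconsistency",
                             "patient_id": int(p), "table": "demographics",
                             "column": "gender", "detail": f"flipped {old}"})

    r_impl = rates.get("implausible_death_date", 0.0)
    if len(demo) and r_impl and len(out.ha_orders):
        first_order = out.ha_orders.groupby("patient_id")["order_day"].min()
        all_ids = np.array(sorted(set(demo["patient_id"])))
        chosen = all_ids[rng.random(len(all_ids)) < r_impl]
        for p in chosen:
            if p not in first_order.index:
                continue
            bad = int(first_order.loc[p]) - 100
            demo.loc[demo["patient_id"] == p, "death_day"] = float(bad)
            log_rows.append({"anomaly": "implausible_death_date",
                             "patient_id": int(p), "table": "demographics",
                             "column": "death_day", "detail": f"set to {bad}"})

    log = pd.DataFrame(log_rows, columns=["anomaly", "patient_id", "table",
                                          "column", "detail"])
    return out, log


@dataclasses.dataclass
class TruePersistence:
    """Generator-implied persistence probability with Monte-Carlo error."""
    estimate: float
    se: float
    n_rep: int
    method: str

    def __float__(self) -> float:
        return self.estimate


def true_persistence(config: CohortConfig, t_eval: int,
                     dose_days: int = 183, gap_days: int = 365,
                     n_rep: int = 100_000,
                     seed: Optional[int] = None) -> TruePersistence:
    """Persistence probability implied by the generator's latent process.

    This is the oracle the measured pipeline is compared against: it
    simulates the discontinuation mixture and the truncated log-normal gap
    process directly (no tables, no linkage, no cleaning) and applies the
    persistence definition T < t_last + D_dose + G_acc with the fitting-day
    order at t = 0.  Death and the observation horizon are not simulated:
    the cohort estimate excludes patients not surviving/observed through T,
    and both processes are independent of discontinuation.

    Closed forms cover two regimes: T below the dose-plus-gap threshold is
    always persistent, and a cohort of never-discontinuers with gaps capped
    below the threshold is persistent at every T.
    """
    if t_eval < 0:
        raise ValueError(f"t_eval must be >= 0, got {t_eval}")
    threshold = dose_days + gap_days
    if t_eval < threshold:
        return TruePersistence(1.0, 0.0, 0, "analytic")
    d = config.discontinuation
    if d.never_fraction == 1.0 and config.inter_battery_gap.max_days < threshold:
        return TruePersistence(1.0, 0.0, 0, "analytic")

    rng = np.random.default_rng(config.seed + 7919 if seed is None else seed)
    prev = np.array([p for _, p in
                     sorted(config.chronic_prevalence.by_system.items())])
    k = (rng.random((n_rep, len(prev))) < prev).sum(axis=1)
    tau = _sample_discontinuation(rng, config, k)

    t = np.zeros(n_rep, dtype=np.int64)
    t_last = np.zeros(n_rep, dtype=np.int64)
    active = np.ones(n_rep, dtype=bool)
    cutoff = np.minimum(tau, float(t_eval))
    guard = int(t_eval / config.inter_battery_gap.min_days) + 5
    for _ in range(guard):
        if not active.any():
            break
        t_next = t + _sample_gaps(rng, config, n_rep)
        ok = active & (t_next < cutoff)
        t_last[ok] = t_next[ok]
        t = np.where(ok, t_next, t)
        active = ok
    persistent = t_eval < t_last + threshold
    p = float(persistent.mean())
    se = math.sqrt(p * (1.0 - p) / n_rep)
    return TruePersistence(p, se, n_rep, "monte_carlo")
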