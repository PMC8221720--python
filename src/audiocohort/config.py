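"""Configuration models for the synthetic cohort generator and the pipeline.

Defaults are calibrated to the descriptive statistics of the study system the
generator emulates: a predominantly male (98.4%) hearing-aid cohort with mean
age near 70.6 years, mean four-frequency pure-tone averages of 49.9 dB HL
(left) and 48.7 dB HL (right) with SD 16.8 dB, 14.6% clinically relevant
asymmetry of which 57.7% left-worse, a mean HA-order-to-first-battery-order
lag of 42 days (SD 46.6), right-skewed inter-battery gaps with median near
the 6-month supply period (7.8 months), roughly one fifth of patients
returning an IOI-HA survey, 78.6% audiogram availability, and a two-year
battery-order persistence near 63%.
"""

from __future__ import annotations

import json
import pathlib
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class AgeComponent(BaseModel):
    """One normal component of the (non-unimodal) age-at-order mixture."""
    mean: float = Field(gt=0)
    sd: float = Field(gt=0)
    weight: float = Field(ge=0, le=1)


class Discontinuation(BaseModel):
    """Mixture model of hearing-aid abandonment.

    A fraction ``never_fraction`` of patients never discontinue; the rest
    discontinue at an exponentially distributed time after fitting with rate
    ``hazard_per_year``.  ``morbidity_coupling`` is an optional log-hazard
    coefficient per chronic body system above the cohort mean (0 = no link).
    """
    never_fraction: float = Field(ge=0, le=1, default=0.45)
    hazard_per_year: float = Field(gt=0, default=1.23)
    morbidity_coupling: float = 0.0


class OrderToFirstBattery(BaseModel):
    mean_days: float = Field(gt=0, default=42.0)
    sd_days: float = Field(gt=0, default=46.6)


class InterBatteryGap(BaseModel):
    """Log-normal inter-order gap, truncated so continuing users never lapse.

    ``max_days`` caps gaps below the dose-plus-acceptable-gap horizon
    (183 + 365 = 548 days): a patient who is still using the device reorders
    before an 18-month supply lapse, so non-persistence identifies true
    discontinuation in the synthetic process.
    """
    median_days: float = Field(gt=0, default=237.0)
    log_sd: float = Field(gt=0, default=0.55)
    min_days: int = Field(ge=1, default=14)
    max_days: int = Field(ge=1, default=540)


class ChronicPrevalence(BaseModel):
    """Per-body-system chronic-condition prevalence and code counts.

    When a system is affected, the number of chronic codes assigned in the
    12-month pre-order window is ``1 + Poisson(extra_codes_mean)``.
    """
    by_system: dict[int, float] = Field(default_factory=lambda: {
        1: 0.04, 2: 0.12, 3: 0.45, 4: 0.08, 5: 0.30, 6: 0.15,
        7: 0.55, 8: 0.20, 9: 0.20, 10: 0.20, 11: 0.001, 12: 0.10,
        13: 0.35, 14: 0.01, 15: 0.001, 16: 0.15, 17: 0.10, 18: 0.15,
    })
    extra_codes_mean: float = Field(ge=0, default=2.0)
    out_of_window_mean: float = Field(ge=0, default=0.8)
    noise_codes_mean: float = Field(ge=0, default=1.5)

    @field_validator("by_system")
    @classmethod
    def _systems_valid(cls, v: dict[int, float]) -> dict[int, float]:
        for sys_id, p in v.items():
            if not 1 <= sys_id <= 18:
                raise ValueError(f"by_system: body system {sys_id} outside 1..18")
            if not 0 <= p <= 1:
                raise ValueError(f"by_system[{sys_id}]: probability {p} outside [0,1]")
        return v


#: Per-anomaly injection probabilities (per eligible unit: audiometric entry,
#: multi-record patient, or patient respectively).
DEFAULT_ANOMALY_RATES = {
    "above_limit_code": 0.0134,
    "ambiguous_nonnumeric": 0.0002,
    "not_divisible_by_5": 0.0002,
    "duplicate_demographic_inconsistency": 0.0014,
    "implausible_death_date": 0.0001,
}

KNOWN_ANOMALIES = frozenset(DEFAULT_ANOMALY_RATES)


class CohortConfig(BaseModel):
    """Full parameterisation of one synthetic cohort."""

    n_patients: int = Field(ge=0, default=2000)
    seed: int = 0

    male_fraction: float = Field(ge=0, le=1, default=0.984)
    age_mixture: list[AgeComponent] = Field(default_factory=lambda: [
        AgeComponent(mean=65.0, sd=10.0, weight=0.55),
        AgeComponent(mean=78.0, sd=9.0, weight=0.45),
    ])
    #: per-year death hazard by age band (band lower edges in years)
    death_hazard: dict[int, float] = Field(default_factory=lambda: {
        0: 0.010, 60: 0.025, 70: 0.045, 80: 0.090, 90: 0.180,
    })

    pta_mean_left: float = 49.9
    pta_mean_right: float = 48.7
    pta_sd: float = Field(gt=0, default=16.8)
    asymmetry_prob: float = Field(ge=0, le=1, default=0.146)
    left_worse_prob_given_asym: float = Field(ge=0, le=1, default=0.577)
    audiogram_available_prob: float = Field(ge=0, le=1, default=0.786)
    multiple_audiogram_prob: float = Field(ge=0, le=1, default=0.13)

    discontinuation: Discontinuation = Field(default_factory=Discontinuation)
    order_to_first_battery: OrderToFirstBattery = Field(
        default_factory=OrderToFirstBattery)
    inter_battery_gap: InterBatteryGap = Field(default_factory=InterBatteryGap)
    no_battery_prob: float = Field(ge=0, le=1, default=0.002)

    ioi_response_prob: float = Field(ge=0, le=1, default=0.20)
    duplicate_survey_prob: float = Field(ge=0, le=1, default=0.0001)
    #: probabilities of a 2nd and 3rd HA order per patient
    extra_order_probs: tuple[float, float] = (0.021, 0.001)
    chronic_prevalence: ChronicPrevalence = Field(default_factory=ChronicPrevalence)
    anomaly_rates: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_ANOMALY_RATES))

    #: HA orders fall uniformly in [0, order_window_days] (31 months);
    #: all post-order streams are observed to horizon_days (~69 months).
    order_window_days: int = Field(ge=0, default=944)
    horizon_days: int = Field(gt=0, default=2100)
    new_user_fraction: float = Field(ge=0, le=1, default=0.53)
    multi_station_prob: float = Field(ge=0, le=1, default=0.30)
    inpatient_prob: float = Field(ge=0, le=1, default=0.25)

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        w = sum(c.weight for c in self.age_mixture)
        if self.age_mixture and abs(w - 1.0) > 1e-9:
            raise ValueError(f"age_mixture: weights sum to {w}, expected 1")
        for rate_name, rate in self.anomaly_rates.items():
            if rate_name not in KNOWN_ANOMALIES:
                raise ValueError(f"anomaly_rates: unknown anomaly {rate_name!r}")
            if not 0 <= rate <= 1:
                raise ValueError(f"anomaly_rates[{rate_name}]: {rate} outside [0,1]")
        for band, rate in self.death_hazard.items():
            if rate < 0:
                raise ValueError(f"death_hazard[{band}]: negative rate {rate}")
        return self

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "CohortConfig":
        """Load from a JSON or YAML document mirroring the model."""
        text = pathlib.Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.model_validate(data)


class PipelineConfig(BaseModel):
    """Settings for the end-to-end analysis pipeline."""

    input_dir: Optional[str] = None
    output_dir: Optional[str] = None
    table_format: str = "csv"

    dose_days: int = Field(gt=0, default=183)
    gap_days: int = Field(gt=0, default=365)
    eval_days: int = Field(gt=0, default=730)

    fitting_max_lag: int = Field(gt=0, default=180)
    ioi_min_days: int = Field(ge=0, default=14)
    ioi_max_days: int = Field(gt=0, default=180)

    morbidity_window_days: int = Field(gt=0, default=365)
    morbidity_min_codes: int = Field(ge=1, default=2)
    morbidity_exclude_prefix: str = "389"

    age_band_edges: list[int] = Field(default_factory=lambda: [60, 70, 80, 90])
    stratify_by: list[str] = Field(default_factory=lambda: ["age_band", "user_type"])
    single_order_only: bool = False
    min_stratum_n: int = Field(ge=1, default=200)
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        edges = self.age_band_edges
        if edges != sorted(set(edges)):
            raise ValueError("age_band_edges: must be strictly increasing")
        if self.table_format not in ("csv", "parquet"):
            raise ValueError(f"table_format: {self.table_format!r} not csv|parquet")
        return self

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "PipelineConfig":
        text = pathlib.Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.model_validate(data)
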