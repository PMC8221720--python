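# Methods

This note documents the models, conventions and design choices behind
`audiocohort`: what the pipeline computes, what the synthetic generator
assumes, and where the open design decisions were settled.

## Day/month convention

All dates are integer days from a cohort epoch (2012-04-01 for synthetic
data; CSVs render ISO-8601 dates).  Clinical rules mix month- and
day-denominated constants, so months are converted once via
`days(m) = round(m · 365.25 / 12)`: 6 months = 183 days, 12 months = 365,
18 months = 548, 24 months = 730.  All four derived constants are
configurable (`PipelineConfig.dose_days/gap_days/eval_days`,
`fitting_max_lag`).

## Persistence model

Battery orders are treated as prescription refills.  With the fitting-day
order at `t = 0`, `t_last` the most recent order *strictly* before `T`,
`D_dose = 183` days and `G_acc = 365` days, a patient is persistent at `T`
iff `T < t_last + D_dose + G_acc`.  Consequences and conventions:

* the smallest `T` at which anyone can be non-persistent is
  `D_dose + G_acc` = 548 days (18 months); evaluation defaults to
  `T = 730` days (24 months);
* "before `T`" is strict — an order on day `T` does not rescue persistence
  at `T` (literal reading of "most recent order before T");
* the fitting-day battery order counts as an order at `t = 0`, since the
  fitting date *is* the first battery order (proxy definition);
* cohort persistence excludes patients who died within
  `[fitting, fitting + T)` — the boundary day counts as surviving — and
  patients with implausible dates (death preceding birth or first order);
* per-patient persistence is **not** monotone in `T` for arbitrary
  histories: a patient can lapse and return if an inter-order gap exceeds
  `D_dose + G_acc`.  The non-increasing-curve property holds whenever all
  gaps are below that threshold, which the synthetic generator guarantees
  (see below); the property test is scoped accordingly.
* the medication possession ratio uses the union of supply intervals
  `[t, t + D_dose)` clipped to the observation window — overlapping
  supplies never double-count.  "Compliance" (conformance to prescribed
  dose timing) is deliberately out of scope.

## Fitting-date proxy and user type

A hearing-care event occurs on any date with ≥ 1 code from a configurable
code-list CSV (procedural/ICD-9/ICD-10, with a fitting-indicating subset);
same-date records form one event.  The fitting date of an HA order is the
first battery order on/after it with lag ≤ 180 days; battery orders before
the HA order belong to a prior device and are ignored.  With multiple HA
orders, persistence anchors to the *first* order's fitting date, and a
single-order-patient filter is exposed in `PipelineConfig`.  User type is
`experienced` iff an order strictly precedes the index order (a same-day
pair stays `new`).  The shipped code list is a small synthetic stand-in;
real analyses should supply their own CSV.

## Audiometric cleaning

Raw entries map to values with provenance tags: above-limit tokens
(`NR`, `120+`, `>120`) → 120 dB (`ceiling_substituted`); ambiguous tokens
(`DNT`, `CNT`, `--`), unparsable text, values not divisible by 5, and
values outside [−10, 120] → missing (`set_missing`); empty cells stay
missing as `as_entered`.  Token lists are configurable because the full
token inventory of any given system is site-specific.  Validity requires
numeric thresholds (120 included) at 0.5/1/2/4 kHz in both ears.  Multiple
valid audiograms are averaged cell-wise (a cell is missing only if missing
in all) before the PTA is computed; averaged thresholds may be
non-multiples of 5 — divisibility applies to raw entries only.  Bilateral
4F-PTA is the mean of the two ear PTAs (equal-ear weighting, which equals
the 8-value mean).  `worse_ear` is `none` whenever |diff| < 15 dB.
Bone conduction is out of scope.

## Demographics merge

Per-station duplicate records merge by modal value per field; any
disagreement sets `inconsistent`.  The tie-break — needed because "most
frequent value" can tie — takes the value of the earliest-dated source
record; to make that deterministic the demographics table carries a
per-station `record_date` (registration date).  Records without one rank
last in input order.  "Death preceded the order" is strict: a same-day
death is not implausible.

## IOI-HA

Each survey is assigned to the most recent HA order on/before its return
date; two surveys resolving to one order are both excluded as ambiguous.
The patient-specified completion date governs the 14–180-day (inclusive)
return window, with the system entry date as fallback when completion is
absent — the completion date is the better estimate of when the patient
actually answered.  The total is the sum of items 1–7 (7–35); item 8
(self-rated unaided difficulty) is carried as an ordinal covariate and
never summed.  Surveys assigned to an order without a fitting date (e.g. a
second order, for which no proxy is defined) are excluded with reason
`no_fitting_date`.  Psychometric modelling of the instrument is out of
scope; the total is treated as a single interval scale.

## Multimorbidity

ICD-9 codes are normalized (uppercase, dot removed) and looked up in a
Chronic Condition Indicator table (code → chronic flag, body system 1–18);
unknown codes are non-chronic.  The index counts systems with ≥ 2 chronic
codes dated in the half-open window `[order − 365, order)`; codes with
prefix 389 are removed first so the index stays sensitive to other
nervous-system/sense-organ conditions.  Range 0–18.  The shipped CCI table
(`cci_map_toy.csv`) is a small synthetic stand-in with representative codes
per system; real analyses should load the full AHRQ table.

Condition definitions use prefix and three-digit-category-range matching.
**Caveat:** the shipped illustrative definitions reproduce a published
transposition — "arthritis" carries range 360–379 (standard ICD-9: eye)
and "vision impairment" carries 710–739 (standard: musculoskeletal).  The
defaults follow the source material verbatim rather than silently
correcting it; substantive use should override them.

## Synthetic generator

Defaults emulate the descriptive statistics of a large veteran HA cohort:
98.4% male; a two-component normal age mixture (65 ± 10 y and 78 ± 9 y,
weights 0.55/0.45; mean ≈ 70.9 y) since real age-at-order distributions
are not unimodal; mean 4F-PTA 49.9/48.7 dB HL (SD 16.8) via a sloping
base audiogram plus a patient severity effect; 14.6% latent asymmetry
(≥ 15 dB offsets, 57.7% left-worse); order-to-first-battery delay
N(42, 46.6²) days truncated at 0; inter-battery gaps log-normal with
median 237 days (≈ 7.8 months) and log-SD 0.55; 78.6% audiogram
availability; 20% survey response with 95% of returns inside the 14–180-day
window; per-system chronic prevalences summing to ≈ 3.15 with
`1 + Poisson(2)` in-window codes per affected system, giving a mean
multimorbidity index of ≈ 2.72; age-banded death hazards yielding ≈ 20%
deaths over the observation span.

Discontinuation is a mixture: a never-discontinue point mass
(default 0.45) plus an exponential hazard (default 1.23 / year from
fitting), the simplest family able to match a ≈ 63% two-year persistence
plateau; the hazard default was solved numerically against the generator's
own oracle to hit that plateau.  An optional log-hazard coupling per
chronic body system (`morbidity_coupling`, default 0 — no published value
exists for this joint distribution) lets tests verify directional recovery
of condition-linked discontinuation.

Two structural choices matter for interpretation:

* **Gap truncation.**  Inter-order gaps are clipped to
  `[14, 540]` days, just below the 548-day persistence threshold: a
  patient still using the device reorders before an 18-month lapse, so in
  synthetic data non-persistence identifies true discontinuation exactly,
  and the oracle comparison is clean.  Real data need not satisfy this
  (patients can lapse and return), which is precisely why the persistence
  curve monotonicity property is scoped to gap-capped histories.
  Truncation pulls the realized gap median to ≈ 220 days, slightly below
  the configured 237.
* **Ceiling substitution inflates measured asymmetry.**  Injected
  above-limit entries are replaced by 120 dB during cleaning, which can
  move one ear's PTA by ≈ 15 dB; the measured asymmetry fraction
  (≈ 0.17–0.18) therefore sits above the latent 0.146.  This mirrors what
  ceiling substitution does in real data and is left visible rather than
  compensated.

Anomalies are injected after clean generation (ground truth keeps
pre-anomaly values) at per-unit rates: above-limit 0.0134 per tested entry
(≈ 23.6% of audiograms affected, given ≈ 16 tested cells), ambiguous and
non-divisible 2·10⁻⁴ each (≈ 0.86% of audiograms combined), demographic
inconsistency 1.4·10⁻³ per multi-station patient, implausible death
1·10⁻⁴ per patient.  The three audiometric anomalies are mutually
exclusive per cell, so the injection log reconciles exactly with the
pipeline's substitution counts.

The oracle `true_persistence` simulates the latent discontinuation/gap
process directly (no tables, linkage or cleaning) and applies the
persistence definition; it reports a Monte-Carlo standard error, with
closed forms for the always-persistent regimes.  Death and the horizon are
not simulated because both are independent of discontinuation and the
pipeline estimate conditions on surviving, observed patients.

## What passing tests do and do not show

Parameter-recovery tests (pipeline estimate within 3 combined SE of the
oracle at n = 50,000 for true two-year persistence ≈ 0.40 / 0.633 / 0.90)
validate the *measurement machinery* — linkage, fitting assignment,
exclusion logic, and the persistence rule — under the generator's
assumptions: refill-like ordering with capped gaps, discontinuation
independent of death, no external battery sources.  They do not validate
those assumptions against real cohorts, where supply sharing, non-VA
battery purchases, and informative censoring would bias a refill-based
persistence measure in ways no synthetic check can detect.

## Problem sizes and numerics

Calibration and recovery tests use n = 50,000 patients with fixed seeds
and a 100,000-replicate oracle; structural tests use a few hundred.
Statistical assertions use 3-standard-error bands (binomial or delta-rule
combined).  The exhaustive IOI enumeration covers all 5⁷ item
combinations; multimorbidity rules are enumerated over small instances.
All randomness flows through `numpy.random.default_rng` seeds carried in
the configs; identical (config, seed) pairs reproduce byte-identical
tables.

## Known limitations

* The shipped code list, CCI table and condition definitions are toy
  stand-ins sized for testing, not clinical resources.
* The generator does not model clinic scheduling, device models beyond
  style labels, ICD-10 diagnosis streams, or correlation between survey
  response and outcomes beyond what is configured.
* Persistence at evaluation times approaching the observation horizon is
  right-censored for late-fitted patients; the default 24-month evaluation
  is unaffected, but long `persistence_curve` grids should be read with
  the follow-up truncation in mind.
* The IOI return-window filter uses the completion date; systems whose
  entry lag is large and informative would need the fallback revisited.
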