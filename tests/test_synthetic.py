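"""Generator contracts: determinism, degenerate configs, anomaly injection,
marginal calibration, and the persistence oracle."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

import audiocohort as ac
from audiocohort.config import Discontinuation, InterBatteryGap
from audiocohort.synthetic import inject_anomalies, true_persistence


class TestGenerateContracts:
    def test_empty_cohort(self):
        cohort, truth = ac.generate_cohort(ac.CohortConfig(n_patients=0))
        for _, df in cohort.tables():
            assert df.empty
        assert truth.patients.empty

    def test_determinism_and_seed_sensitivity(self):
        cfg = ac.CohortConfig(n_patients=500, seed=42)
        c1, _ = ac.generate_cohort(cfg)
        c2, _ = ac.generate_cohort(ac.CohortConfig(n_patients=500, seed=42))
        for (name, a), (_, b) in zip(c1.tables(), c2.tables()):
            pd.testing.assert_frame_equal(a, b)
        c3, _ = ac.generate_cohort(ac.CohortConfig(n_patients=500, seed=43))
        assert not c3.battery_orders.equals(c1.battery_orders)

    def test_referential_integrity(self, small_cohort):
        _, cohort, _ = small_cohort
        cohort.validate()     # raises on orphan ids

    def test_conservation_of_patients(self, small_cohort):
        cfg, cohort, _ = small_cohort
        with_batt = cohort.battery_orders["patient_id"].nunique()
        without = cfg.n_patients - with_batt
        assert with_batt + without == cfg.n_patients
        assert cohort.n_patients == cfg.n_patients

    def test_never_discontinue_keeps_ordering(self):
        """never_fraction=1: orders continue to death/horizon and the
        ground truth has no finite discontinuation day."""
        cfg = ac.CohortConfig(
            n_patients=300, seed=3,
            discontinuation=Discontinuation(never_fraction=1.0,
                                            hazard_per_year=1.0))
        cohort, truth = ac.generate_cohort(cfg)
        assert np.isinf(truth.patients["discontinuation_day"]).all()
        # every surviving fitted patient keeps ordering until near horizon
        gt = truth.patients.dropna(subset=["fitting_day"])
        demo = cohort.demographics.groupby("patient_id").first()
        last = cohort.battery_orders.groupby("patient_id")["order_day"].max()
        for pid, row in gt.iterrows():
            p = int(row["patient_id"])
            death = demo.loc[p, "death_day"]
            end = cfg.horizon_days if pd.isna(death) else death
            assert last[p] > end - 2 * cfg.inter_battery_gap.max_days

    def test_orders_only_while_alive_and_before_discontinuation(
            self, small_cohort):
        _, cohort, truth = small_cohort
        gt = truth.patients.set_index("patient_id")
        demo = cohort.demographics.groupby("patient_id").first()
        for pid, days in cohort.battery_orders.groupby("patient_id")["order_day"]:
            fit = gt.loc[pid, "fitting_day"]
            tau = gt.loc[pid, "discontinuation_day"]
            rel = days.to_numpy() - fit
            assert rel.min() == 0
            assert (rel[1:] < tau).all()
            death = demo.loc[pid, "death_day"]
            if not pd.isna(death):
                assert (days.to_numpy() < death).all()

    def test_ioi_rows_always_complete(self, small_cohort):
        _, cohort, _ = small_cohort
        items = cohort.ioi[[f"item{i}" for i in range(1, 9)]]
        assert items.notna().all().all()
        assert items.isin(range(1, 6)).all().all()

    def test_invalid_config_names_offending_field(self):
        with pytest.raises(ValidationError, match="male_fraction"):
            ac.CohortConfig(male_fraction=1.5)
        with pytest.raises(ValidationError, match="weights sum"):
            ac.CohortConfig(age_mixture=[
                {"mean": 70, "sd": 10, "weight": 0.6},
                {"mean": 80, "sd": 8, "weight": 0.6}])
        with pytest.raises(ValidationError, match="anomaly"):
            ac.CohortConfig(anomaly_rates={"bogus": 0.1})


class TestInjectAnomalies:
    def test_zero_rates_identity(self, small_cohort):
        _, cohort, _ = small_cohort
        out, log = inject_anomalies(cohort, {}, seed=1)
        for (_, a), (_, b) in zip(cohort.tables(), out.tables()):
            pd.testing.assert_frame_equal(a, b)
        assert log.empty

    def test_unknown_key_rejected(self, small_cohort):
        _, cohort, _ = small_cohort
        with pytest.raises(ValueError, match="bogus"):
            inject_anomalies(cohort, {"bogus": 0.5}, seed=1)

    def test_saturating_above_limit_rate(self, small_cohort):
        _, cohort, _ = small_cohort
        out, _ = inject_anomalies(cohort, {"above_limit_code": 1.0}, seed=1)
        cols = [c for c in out.audiometry.columns
                if c not in ("patient_id", "exam_day")]
        vals = out.audiometry[cols].to_numpy(dtype=object)
        nonempty = vals[vals != ""]
        assert (nonempty == "NR").all()

    def test_injected_count_matches_independent_recount(self, small_cohort):
        """Log size equals a direct tally of non-divisible entries in the
        output, and is binomially plausible for the eligible-cell count."""
        _, cohort, truth = small_cohort
        rate = 0.1
        clean = truth.audiometry_true     # pre-anomaly tables as baseline
        out, log = inject_anomalies(
            ac.RawCohort(**{n: (clean.copy() if n == "audiometry" else d.copy())
                            for n, d in cohort.tables()}),
            {"not_divisible_by_5": rate}, seed=123)
        cols = [c for c in clean.columns if c not in ("patient_id", "exam_day")]
        vals = pd.concat([out.audiometry[c] for c in cols])
        numeric = pd.to_numeric(vals, errors="coerce")
        recount = int((numeric.notna() & ((numeric % 5) != 0)).sum())
        n_log = int((log["anomaly"] == "not_divisible_by_5").sum())
        assert recount == n_log
        n_eligible = int((pd.concat([clean[c] for c in cols]) != "").sum())
        se = np.sqrt(rate * (1 - rate) * n_eligible)
        assert abs(n_log - rate * n_eligible) <= 4 * se


class TestTruePersistence:
    def test_never_discontinue_is_one_everywhere(self):
        cfg = ac.CohortConfig(
            discontinuation=Discontinuation(never_fraction=1.0,
                                            hazard_per_year=1.0))
        for t in (100, 548, 730, 2000):
            assert true_persistence(cfg, t).estimate == 1.0

    def test_below_threshold_always_one(self):
        cfg = ac.CohortConfig(
            discontinuation=Discontinuation(never_fraction=0.0,
                                            hazard_per_year=50.0))
        assert true_persistence(cfg, 547).estimate == 1.0
        assert true_persistence(cfg, 547).method == "analytic"

    def test_monte_carlo_known_construction(self):
        """Degenerate 180-day gaps with P(discontinue by day 182) = 1/2:
        orders fall at 0, 180, 360, ...; persistence at 730 requires the
        day-360 order (180 + 548 = 728 < 730), which occurs iff tau > 360,
        so P = 2^(-360/182)."""
        hazard = np.log(2.0) / (182.0 / 365.25)
        cfg = ac.CohortConfig(
            discontinuation=Discontinuation(never_fraction=0.0,
                                            hazard_per_year=hazard),
            inter_battery_gap=InterBatteryGap(median_days=180.0, log_sd=1e-9,
                                              min_days=180, max_days=180))
        res = true_persistence(cfg, 730, n_rep=100_000, seed=5)
        expected = np.exp(-360.0 * np.log(2.0) / 182.0)
        assert res.method == "monte_carlo"
        assert abs(res.estimate - expected) <= 4 * max(res.se, 1e-4)


def test_marginal_calibration(big_default_cohort):
    """Male, audiogram-availability, IOI-response and death fractions all
    land within 3 Monte-Carlo SE of their configured/analytic values."""
    cfg, cohort, truth = big_default_cohort
    n = cfg.n_patients
    demo = cohort.demographics.groupby("patient_id").first()

    male = (demo["gender"] == "M").mean()
    se = np.sqrt(cfg.male_fraction * (1 - cfg.male_fraction) / n)
    assert abs(male - cfg.male_fraction) <= 3 * se

    p_audio = cfg.audiogram_available_prob
    audio = cohort.audiometry["patient_id"].nunique() / n
    se = np.sqrt(p_audio * (1 - p_audio) / n)
    assert abs(audio - p_audio) <= 3 * se

    fitted = set(cohort.battery_orders["patient_id"])
    resp = cohort.ioi["patient_id"].nunique() / len(fitted)
    p_resp = cfg.ioi_response_prob
    se = np.sqrt(p_resp * (1 - p_resp) / len(fitted))
    assert abs(resp - p_resp) <= 3 * se

    # death: compare with the per-patient analytic exponential probability
    first_order = cohort.ha_orders.groupby("patient_id")["order_day"].min()
    ages = (first_order - demo["birth_day"]) / 365.25
    bands = sorted(cfg.death_hazard.items())
    rates = pd.Series(bands[0][1], index=ages.index, dtype=float)
    for edge, rate in bands:
        rates[ages >= edge] = rate
    t_years = (cfg.horizon_days - first_order) / 365.25
    p_die = 1.0 - np.exp(-rates * t_years)
    # a handful of injected implausible death dates perturb the count
    n_impl = (truth.anomaly_log["anomaly"] == "implausible_death_date").sum()
    observed = demo["death_day"].notna().sum() - n_impl
    se = np.sqrt((p_die * (1 - p_die)).sum())
    assert abs(observed - p_die.sum()) <= 3 * se + n_impl
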