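"""Persistence formula, possession ratio, and their brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from audiocohort.persistence import (BatteryOrderHistory, PersistenceParams,
                                     cohort_persistence,
                                     is_persistent,
                                     medication_possession_ratio,
                                     persistence_curve, persistence_flags)


def day_step_persistent(rel_days, t_eval, dose, gap):
    """Independent day-stepping oracle: walk every day, track last order."""
    orders = set(int(d) for d in rel_days)
    last = None
    for day in range(0, t_eval):
        if day in orders:
            last = day
    assert last is not None
    return t_eval < last + dose + gap


def day_count_mpr(rel_days, window, dose):
    """Independent day-count oracle for the possession ratio."""
    covered = sum(1 for day in range(window)
                  if any(t <= day < t + dose for t in rel_days))
    return covered / window


def history(rel_days, fitting=1000):
    return BatteryOrderHistory(patient_id=1, fitting_day=fitting,
                               order_days=np.asarray(rel_days) + fitting)


class TestIsPersistent:
    def test_single_fitting_order_threshold(self, params):
        """A fitting-day-only history survives until dose+gap (548 d)."""
        h = history([0])
        assert is_persistent(h, params, t_eval=547)
        assert not is_persistent(h, params, t_eval=548)

    def test_reorder_extends_persistence(self, params):
        assert is_persistent(history([0, 400]), params, t_eval=730)

    @pytest.mark.parametrize("rel_days,t_eval", [
        ([0, 200, 500], 730), ([0], 548), ([0], 547),
        ([0, 100, 700], 1200), ([0, 182], 730), ([0, 183], 730),
    ])
    def test_matches_day_stepping_oracle(self, rel_days, t_eval, params):
        expected = day_step_persistent(rel_days, t_eval,
                                       params.dose_days, params.gap_days)
        assert is_persistent(history(rel_days), params, t_eval) == expected

    def test_order_on_eval_day_does_not_count(self, params):
        """'Most recent order before T' is strict: day-T orders don't rescue."""
        assert not is_persistent(history([0, 548]), params, t_eval=548)

    def test_formula_oracle_equivalence_random_histories(self, params):
        """Formula agrees with brute-force day simulation on 10,000 histories."""
        rng = np.random.default_rng(42)
        for _ in range(10_000):
            n = rng.poisson(4) + 1
            rel = np.unique(np.concatenate(
                [[0], rng.integers(1, 1200, n)]))
            t_eval = int(rng.integers(1, 1500))
            assert is_persistent(history(rel), params, t_eval) == \
                day_step_persistent(rel, t_eval, params.dose_days,
                                    params.gap_days)

    @given(rel=st.lists(st.integers(1, 2000), max_size=8),
           t_eval=st.integers(1, 2500), k=st.integers(1, 4))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_scale_invariance(self, rel, t_eval, k):
        """Scaling all day quantities by a constant preserves every flag."""
        params = PersistenceParams()
        h1 = history(sorted(set([0] + rel)))
        p1 = PersistenceParams(dose_days=params.dose_days * k,
                               gap_days=params.gap_days * k,
                               eval_days=params.eval_days * k)
        h2 = history([d * k for d in sorted(set([0] + rel))])
        assert is_persistent(h1, params, t_eval) == \
            is_persistent(h2, p1, t_eval * k)

    @given(rel=st.lists(st.integers(1, 2000), max_size=8),
           extra=st.integers(1, 2000), t_eval=st.integers(1, 2500))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_adding_order_never_hurts(self, rel, extra, t_eval):
        params = PersistenceParams()
        base = sorted(set([0] + rel))
        before = is_persistent(history(base), params, t_eval)
        after = is_persistent(history(sorted(set(base + [extra]))),
                              params, t_eval)
        assert after >= before


class TestMPR:
    @pytest.mark.parametrize("rel,window,expected", [
        ([0], 183, 1.0),
        ([0], 366, 0.5),
        ([0, 100], 366, 283 / 366),   # overlapping supplies union, not sum
    ])
    def test_known_values(self, rel, window, expected, params):
        assert medication_possession_ratio(history(rel), window, params) == \
            pytest.approx(expected)

    def test_against_day_count_oracle(self, params):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = rng.poisson(3) + 1
            rel = np.unique(np.concatenate([[0], rng.integers(1, 900, n)]))
            window = int(rng.integers(30, 1100))
            got = medication_possession_ratio(history(rel), window, params)
            assert got == pytest.approx(
                day_count_mpr(rel, window, params.dose_days))

    def test_never_exceeds_one(self, params):
        assert medication_possession_ratio(
            history([0, 1, 2, 3]), 100, params) == 1.0


def _demo(pids, death=None):
    return pd.DataFrame({"patient_id": pids,
                         "death_day": death if death is not None
                         else [np.nan] * len(pids),
                         "implausible": False})


class TestCohortPersistence:
    def test_all_lapsed(self, params):
        hs = [history([0], fitting=0) for _ in range(5)]
        for i, h in enumerate(hs):
            h.patient_id = i
        res = cohort_persistence(hs, _demo(range(5)), params, t_eval=730)
        assert res.proportion == 0.0 and res.n_included == 5

    def test_all_persistent(self, params):
        hs = []
        for i in range(5):
            h = history([0, 400], fitting=0)
            h.patient_id = i
            hs.append(h)
        res = cohort_persistence(hs, _demo(range(5)), params)
        assert res.proportion == 1.0

    def test_death_exclusion_window(self, params):
        """Dying on day fitting+729 excludes; fitting+730 keeps the patient."""
        hs = []
        for i in range(2):
            h = history([0, 400], fitting=0)
            h.patient_id = i
            hs.append(h)
        demo = _demo([0, 1], death=[729.0, 730.0])
        res = cohort_persistence(hs, demo, params, t_eval=730)
        assert res.n_included == 1 and res.n_excluded_death == 1

    def test_empty_inclusion_raises(self, params):
        h = history([0], fitting=0)
        h.patient_id = 0
        with pytest.raises(ValueError):
            cohort_persistence([h], _demo([0], death=[10.0]), params)


class TestPersistenceCurve:
    def test_below_threshold_everyone_persistent(self, params):
        hs = []
        for i in range(10):
            h = history([0], fitting=0)
            h.patient_id = i
            hs.append(h)
        curve = persistence_curve(hs, _demo(range(10)), params,
                                  t_grid=[100, 300, 547])
        assert all(p == 1.0 for _, p, _ in curve)

    def test_single_point_matches_cohort_value(self, params):
        hs = []
        for i in range(4):
            h = history([0, 300], fitting=0)
            h.patient_id = i
            hs.append(h)
        (t, p, n), = persistence_curve(hs, _demo(range(4)), params, [730])
        assert p == cohort_persistence(hs, _demo(range(4)), params, 730).proportion

    def test_nonincreasing_for_gap_capped_histories(self, params):
        """With inter-order gaps below dose+gap, lapses are permanent, so
        the death-free cohort curve never increases."""
        rng = np.random.default_rng(9)
        hs = []
        for i in range(1000):
            gaps = rng.integers(30, 540, rng.poisson(3) + 1)
            rel = np.concatenate([[0], np.cumsum(gaps)])
            h = history(rel, fitting=0)
            h.patient_id = i
            hs.append(h)
        grid = list(range(548, 2400, 150))
        curve = persistence_curve(hs, _demo(range(1000)), params, grid)
        props = [p for _, p, _ in curve]
        assert all(a >= b for a, b in zip(props, props[1:]))


class TestVectorizedFlags:
    def test_matches_scalar_path(self, params):
        rng = np.random.default_rng(5)
        fit_rows, bat_rows = [], []
        hs = []
        for i in range(200):
            fitting = int(rng.integers(0, 500))
            gaps = rng.integers(20, 700, rng.poisson(3) + 1)
            rel = np.unique(np.concatenate([[0], np.cumsum(gaps)]))
            h = history(rel, fitting=fitting)
            h.patient_id = i
            hs.append(h)
            fit_rows.append({"patient_id": i, "fitting_day": fitting})
            bat_rows += [{"patient_id": i, "order_day": int(d)}
                         for d in h.order_days]
        flags = persistence_flags(pd.DataFrame(fit_rows),
                                  pd.DataFrame(bat_rows), params)
        for h in hs:
            assert flags.loc[h.patient_id] == is_persistent(h, params)


class TestHistoryValidation:
    def test_requires_fitting_day_order(self):
        with pytest.raises(ValueError):
            BatteryOrderHistory(patient_id=1, fitting_day=10,
                                order_days=np.array([20, 30]))

    def test_deduplicates_and_sorts(self):
        h = BatteryOrderHistory(patient_id=1, fitting_day=0,
                                order_days=np.array([300, 0, 300, 100]))
        assert list(h.order_days) == [0, 100, 300]
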