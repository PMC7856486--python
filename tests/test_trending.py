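"""Session store, monthly Tukey summaries, drift regression and alerts."""

import datetime
import itertools

import numpy as np
import pandas as pd
import pytest

import protondqa as pq
from protondqa.trending import (
    DAYS_PER_MONTH,
    DriftEstimate,
    SessionStore,
    box_stats,
    drift_alerts,
    drift_regression,
    monthly_summary,
)


def store_with(tmp_path, rows):
    store = SessionStore(tmp_path / "store.csv")
    df = pd.DataFrame(rows, columns=["date", "room", "metric", "deviation",
                                     "units", "status"])
    store.append_rows(df)
    return store


def daily_rows(values, metric="output", room="TR2",
               start=datetime.date(2024, 1, 1)):
    return [
        (start + datetime.timedelta(days=k), room, metric, v, "%", "pass")
        for k, v in enumerate(values)
    ]


class TestSessionStore:
    def test_append_session_row_count(self, tmp_path, nominal_grid, commissioned):
        baseline, cal = commissioned
        session = pq.evaluate_session(nominal_grid, cal, baseline)
        session.date = datetime.date(2024, 3, 1)
        session.room = "TR2"
        store = SessionStore(tmp_path / "s.csv")
        pq.append_session(store, session)
        assert len(store.read()) == len(session.checks) == 3 + 4 * 7 + 6

    def test_duplicate_session_rejected_store_unchanged(self, tmp_path,
                                                        nominal_grid, commissioned):
        baseline, cal = commissioned
        session = pq.evaluate_session(nominal_grid, cal, baseline)
        session.date = datetime.date(2024, 3, 1)
        store = SessionStore(tmp_path / "s.csv")
        pq.append_session(store, session)
        before = store.read()
        with pytest.raises(ValueError, match="duplicate"):
            pq.append_session(store, session)
        assert store.read().equals(before)

    def test_round_trip(self, tmp_path):
        rows = daily_rows([0.5, -0.25, 1.0])
        store = store_with(tmp_path, rows)
        df = store.read()
        assert list(df["deviation"]) == [0.5, -0.25, 1.0]
        assert list(df["date"]) == [r[0] for r in rows]


class TestMonthlySummary:
    def test_hand_computed_quartiles(self, tmp_path):
        store = store_with(tmp_path, daily_rows([1, 2, 3, 4, 5]))
        (m,) = monthly_summary(store, "output", "TR2")
        assert (m.median, m.q25, m.q75) == (3, 2, 4)
        assert (m.whisker_lo, m.whisker_hi) == (-1, 7)
        assert m.outliers == []
        assert m.n == 5

    def test_constant_month(self, tmp_path):
        store = store_with(tmp_path, daily_rows([0.7] * 4))
        (m,) = monthly_summary(store, "output", "TR2")
        assert m.median == m.q25 == m.q75 == 0.7
        assert m.whisker_lo == m.whisker_hi == 0.7
        assert m.outliers == []

    def test_single_value(self, tmp_path):
        store = store_with(tmp_path, daily_rows([1.3]))
        (m,) = monthly_summary(store, "output", "TR2")
        assert m.median == 1.3 and m.n == 1

    def test_outliers_outside_fences(self, tmp_path):
        store = store_with(tmp_path, daily_rows([1, 2, 3, 4, 5, 40]))
        (m,) = monthly_summary(store, "output", "TR2")
        assert m.outliers == [40]

    def test_partition_complete_across_months(self, tmp_path):
        values = list(range(70))
        store = store_with(tmp_path, daily_rows(values))
        months = monthly_summary(store, "output", "TR2")
        assert sum(m.n for m in months) == len(values)
        assert [m.month for m in months] == ["2024-01", "2024-02", "2024-03"]

    def test_quartiles_match_order_statistics_oracle(self, tmp_path):
        """Exhaustive check against direct interpolation of order statistics
        for every multiset of {0,1,2,3} values up to length 8."""

        def oracle_quantile(sorted_vals, p):
            h = (len(sorted_vals) - 1) * p
            lo = int(np.floor(h))
            hi = min(lo + 1, len(sorted_vals) - 1)
            return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

        for n in range(1, 9):
            for combo in itertools.combinations_with_replacement([0, 1, 2, 3], n):
                med, q25, q75, lo, hi, outl = box_stats(list(combo))
                s = sorted(combo)
                assert q25 == pytest.approx(oracle_quantile(s, 0.25))
                assert med == pytest.approx(oracle_quantile(s, 0.50))
                assert q75 == pytest.approx(oracle_quantile(s, 0.75))
                iqr = q75 - q25
                assert lo == pytest.approx(q25 - 1.5 * iqr)
                assert hi == pytest.approx(q75 + 1.5 * iqr)
                assert outl == sorted(v for v in combo if v < lo or v > hi)
                assert q25 <= med <= q75

    def test_empty_selection(self, tmp_path):
        store = store_with(tmp_path, daily_rows([1.0]))
        assert monthly_summary(store, "nope", "TR2") == []


class TestDriftRegression:
    def test_recovers_injected_monthly_rate(self, tmp_path):
        # 180 consecutive days falling at 0.76% per month, noiseless
        rate_per_day = -0.76 / DAYS_PER_MONTH
        store = store_with(tmp_path,
                           daily_rows([k * rate_per_day for k in range(180)],
                                      metric="energy_dose"))
        est = drift_regression(store, "energy_dose", "TR2")
        assert est.slope_pct_per_month == pytest.approx(-0.76, abs=1e-9)
        assert est.slope_se == pytest.approx(0.0, abs=1e-7)
        assert est.n == 180

    def test_constant_series_zero_slope(self, tmp_path):
        store = store_with(tmp_path, daily_rows([0.4] * 10))
        est = drift_regression(store, "output", "TR2")
        assert est.slope_pct_per_month == 0.0

    def test_two_points_rejected(self, tmp_path):
        store = store_with(tmp_path, daily_rows([0.0, 1.0]))
        with pytest.raises(ValueError, match="3 rows"):
            drift_regression(store, "output", "TR2")

    def test_fewer_than_three_in_window_rejected(self, tmp_path):
        store = store_with(tmp_path, daily_rows([0.0, 1.0, 2.0, 3.0]))
        window = (datetime.date(2024, 1, 1), datetime.date(2024, 1, 2))
        with pytest.raises(ValueError, match="3 rows"):
            drift_regression(store, "output", "TR2", window)

    def test_window_restricts_rows(self, tmp_path):
        store = store_with(tmp_path, daily_rows(list(np.linspace(0, -3, 60))))
        window = (datetime.date(2024, 1, 1), datetime.date(2024, 1, 15))
        est = drift_regression(store, "output", "TR2", window)
        assert est.n == 15
        assert est.window == window

    def test_ci_covers_true_slope(self, tmp_path, rng):
        """95% CI coverage of the true slope over noisy replicates
        (reduced replicate count here; 500 run in acceptance)."""
        true_daily = 0.02
        true_monthly = true_daily * DAYS_PER_MONTH
        t = np.arange(40, dtype=float)
        n_rep = 100
        rows = []
        for r in range(n_rep):
            y = true_daily * t + rng.normal(0, 0.5, t.size)
            rows += daily_rows(y, metric=f"m{r}")
        store = store_with(tmp_path, rows)
        covered = sum(
            (lambda e: e.ci95_lo <= true_monthly <= e.ci95_hi)(
                drift_regression(store, f"m{r}", "TR2"))
            for r in range(n_rep)
        )
        assert covered / n_rep >= 0.90


class TestDriftAlerts:
    def test_significant_large_drift_alerts(self):
        est = DriftEstimate(-0.76, 0.0, 0.02, -0.80, -0.72, 180,
                            (datetime.date(2024, 1, 1), datetime.date(2024, 6, 28)))
        (alert,) = drift_alerts({("energy_dose", "TR2"): est}, 0.5)
        assert alert.metric == "energy_dose"
        assert alert.slope_pct_per_month == -0.76

    def test_ci_spanning_zero_suppresses(self):
        est = DriftEstimate(-0.76, 0.0, 0.4, -1.6, 0.1, 20,
                            (datetime.date(2024, 1, 1), datetime.date(2024, 1, 20)))
        assert drift_alerts({("energy_dose", "TR2"): est}, 0.5) == []

    def test_small_slope_suppresses(self):
        est = DriftEstimate(0.1, 0.0, 0.01, 0.08, 0.12, 50,
                            (datetime.date(2024, 1, 1), datetime.date(2024, 2, 19)))
        assert drift_alerts({("output", "TR1"): est}, 0.5) == []
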