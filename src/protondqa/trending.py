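"""Longitudinal trending: session store, monthly box statistics, drift.

Daily check deviations accumulate in an append-only CSV store (columns
``date,room,metric,deviation,units,status``; one row per check, unique on
(date, room, metric)).  Two summaries reproduce the auto-trending
analysis:

* monthly Tukey box statistics — median, quartiles by linear interpolation
  of order statistics, whiskers drawn at the exact fences q25 - 1.5*IQR
  and q75 + 1.5*IQR, values outside the fences listed as outliers;
* drift regression — ordinary least squares of deviation against time,
  reported as a slope in percent per month using the mean Gregorian month
  of 30.4375 days, with standard error and a 95% confidence interval on
  n - 2 degrees of freedom.  An alert fires when the slope magnitude
  reaches a threshold and the interval excludes zero.
"""

from __future__ import annotations

import datetime as _dt
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .evaluation import DQASession

__all__ = [
    "DAYS_PER_MONTH",
    "SessionStore",
    "MonthlySummary",
    "DriftEstimate",
    "DriftAlert",
    "append_session",
    "monthly_summary",
    "drift_regression",
    "drift_alerts",
]

DAYS_PER_MONTH = 30.4375  # mean Gregorian month
_COLUMNS = ["date", "room", "metric", "deviation", "units", "status"]


class SessionStore:
    """Append-only CSV store of per-check deviations."""

    def __init__(self, path):
        self.path = os.fspath(path)
        if not os.path.exists(self.path):
            pd.DataFrame(columns=_COLUMNS).to_csv(self.path, index=False)

    def read(self) -> pd.DataFrame:
        df = pd.read_csv(self.path, dtype={"room": str, "metric": str})
        df["date"] = pd.to_datetime(df["date"]).dt.date
        return df

    def append_rows(self, rows: pd.DataFrame) -> None:
        existing = self.read()
        key = ["date", "room", "metric"]
        merged = pd.concat([existing[key], rows[key]])
        if merged.duplicated().any():
            dupe = merged[merged.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate entry for ({dupe['date']}, {dupe['room']}, "
                f"{dupe['metric']}); store rows are immutable"
            )
        rows = rows.copy()
        rows["date"] = rows["date"].astype(str)
        rows[_COLUMNS].to_csv(self.path, mode="a", header=False, index=False)


@dataclass
class MonthlySummary:
    """Tukey box-whisker statistics for one calendar month."""

    month: str  # "YYYY-MM"
    n: int
    median: float
    q25: float
    q75: float
    whisker_lo: float  # q25 - 1.5 * IQR
    whisker_hi: float  # q75 + 1.5 * IQR
    outliers: list[float]


@dataclass
class DriftEstimate:
    """OLS drift of a metric's deviation, in percent (or mm) per month."""

    slope_pct_per_month: float
    intercept: float
    slope_se: float
    ci95_lo: float
    ci95_hi: float
    n: int
    window: tuple[_dt.date, _dt.date]


@dataclass
class DriftAlert:
    metric: str
    room: str
    slope_pct_per_month: float
    ci95_lo: float
    ci95_hi: float


def append_session(store: SessionStore, session: DQASession) -> None:
    """Log one evaluated session: one store row per check result."""
    if session.date is None:
        raise ValueError("session has no date")
    rows = pd.DataFrame(
        [
            {
                "date": session.date,
                "room": session.room,
                "metric": c.name,
                "deviation": c.deviation,
                "units": c.units,
                "status": c.status,
            }
            for c in session.checks
        ]
    )
    store.append_rows(rows)


def _select(store: SessionStore, metric: str, room: str,
            window: tuple[_dt.date, _dt.date] | None = None) -> pd.DataFrame:
    df = store.read()
    df = df[(df["metric"] == metric) & (df["room"] == room)]
    if window is not None:
        lo, hi = window
        df = df[(df["date"] >= lo) & (df["date"] <= hi)]
    return df.dropna(subset=["deviation"]).sort_values("date")


def box_stats(values) -> tuple[float, float, float, float, float, list[float]]:
    """(median, q25, q75, whisker_lo, whisker_hi, outliers) of a sample.

    Quartiles by linear interpolation of order statistics; whiskers at the
    exact Tukey fences.
    """
    v = np.asarray(values, dtype=float)
    q25, med, q75 = np.percentile(v, [25, 50, 75], method="linear")
    iqr = q75 - q25
    lo = q25 - 1.5 * iqr
    hi = q75 + 1.5 * iqr
    outliers = sorted(float(x) for x in v[(v < lo) | (v > hi)])
    return float(med), float(q25), float(q75), float(lo), float(hi), outliers


def monthly_summary(store: SessionStore, metric: str, room: str) -> list[MonthlySummary]:
    """Per-calendar-month box statistics of one metric in one room."""
    df = _select(store, metric, room)
    if df.empty:
        return []
    months = df["date"].map(lambda d: f"{d.year:04d}-{d.month:02d}")
    out = []
    for month, grp in df.groupby(months, sort=True):
        med, q25, q75, lo, hi, outl = box_stats(grp["deviation"].to_numpy())
        out.append(MonthlySummary(month, len(grp), med, q25, q75, lo, hi, outl))
    return out


def drift_regression(
    store: SessionStore,
    metric: str,
    room: str,
    window: tuple[_dt.date, _dt.date] | None = None,
) -> DriftEstimate:
    """OLS drift of a metric's deviation over a date window.

    Time is measured in days since the window start; the daily slope is
    converted to a monthly one with the 30.4375 days/month factor.
    """
    df = _select(store, metric, room, window)
    if len(df) < 3:
        raise ValueError("drift regression needs at least 3 rows")
    dates = df["date"].to_numpy()
    start = window[0] if window else dates.min()
    end = window[1] if window else dates.max()
    t_days = np.array([(d - start).days for d in dates], dtype=float)
    if np.ptp(t_days) == 0:
        raise ValueError("all rows share one date; zero time variance")
    y = df["deviation"].to_numpy(dtype=float)
    res = _stats.linregress(t_days, y)
    n = len(y)
    slope_m = res.slope * DAYS_PER_MONTH
    se_m = res.stderr * DAYS_PER_MONTH
    tcrit = _stats.t.ppf(0.975, n - 2)
    return DriftEstimate(
        slope_pct_per_month=float(slope_m),
        intercept=float(res.intercept),
        slope_se=float(se_m),
        ci95_lo=float(slope_m - tcrit * se_m),
        ci95_hi=float(slope_m + tcrit * se_m),
        n=n,
        window=(start, end),
    )


def drift_alerts(
    estimates: dict[tuple[str, str], DriftEstimate] | list[tuple[str, str, DriftEstimate]],
    threshold_pct_per_month: float,
) -> list[DriftAlert]:
    """Alert on drifts both large and statistically established.

    Fires when |slope| >= threshold AND the 95% CI excludes zero.
    Accepts a mapping ``{(metric, room): estimate}`` or an equivalent list
    of triples.
    """
    if not threshold_pct_per_month > 0:
        raise ValueError("threshold must be positive")
    if isinstance(estimates, dict):
        items = [(m, r, e) for (m, r), e in estimates.items()]
    else:
        items = list(estimates)
    alerts = []
    for metric, room, est in items:
        significant = est.ci95_lo > 0 or est.ci95_hi < 0
        if abs(est.slope_pct_per_month) >= threshold_pct_per_month and significant:
            alerts.append(DriftAlert(metric, room, est.slope_pct_per_month,
                                     est.ci95_lo, est.ci95_hi))
    return alerts
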