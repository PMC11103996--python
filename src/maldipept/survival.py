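"""Kaplan-Meier estimation and the two-group log-rank test.

These wrap lifelines: the product-limit estimator with exponential-Greenwood
(log(-log)) confidence bands — whose inversion gives the 95% CI reported for
median survival — and the standard 1-df log-rank chi-square.  Records carry a
time in months, an event flag (1 = progression/death observed, 0 = censored)
and the classifier-assigned group label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times

__all__ = ["KMCurve", "LogRankResult", "km_fit", "logrank_test"]


@dataclass
class KMCurve:
    """A fitted product-limit curve with median survival and its 95% CI."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk_counts: np.ndarray
    median: float | None
    median_ci_low: float | None
    median_ci_high: float | None

    def survival_at(self, t: float) -> float:
        i = int(np.searchsorted(self.event_times, t, side="right")) - 1
        return 1.0 if i < 0 else float(self.survival_probs[i])


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float


def _coerce_records(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(records)
    if "time_months" not in df.columns or "event" not in df.columns:
        raise ValueError("records need 'time_months' and 'event' columns")
    if len(df) == 0:
        raise ValueError("no survival records")
    if (df["time_months"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    return df


def km_fit(records, alpha: float = 0.05) -> KMCurve:
    """Kaplan-Meier product-limit fit.

    The median is the smallest event time at which the estimated survival
    drops to 0.5 or below (undefined — None — if the curve never does); its
    confidence interval comes from inverting the pointwise exponential-
    Greenwood log(-log) bands.
    """
    df = _coerce_records(records)
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(df["time_months"], event_observed=df["event"])
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    surv = np.array([float(kmf.predict(t)) for t in times])
    at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    med = kmf.median_survival_time_
    if np.isinf(med):
        med = ci_lo = ci_hi = None
    else:
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        ci_lo = None if np.isinf(lo) else lo
        ci_hi = None if np.isinf(hi) else hi
        med = float(med)
    return KMCurve(times, surv, at_risk, med, ci_lo, ci_hi)


def logrank_test(records_a, records_b) -> LogRankResult:
    """Two-group log-rank test: chi-square = (sum O - sum E)^2 / sum V with
    hypergeometric expectations at each distinct event time."""
    a = _coerce_records(records_a)
    b = _coerce_records(records_b)
    if int(a["event"].sum() + b["event"].sum()) == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(
        a["time_months"], b["time_months"],
        event_observed_A=a["event"], event_observed_B=b["event"],
    )
    return LogRankResult(float(res.test_statistic), float(res.p_value))


def km_by_group(records, group_col: str = "group") -> dict[str, KMCurve]:
    """Fit one KM curve per group label."""
    df = _coerce_records(records)
    if group_col not in df.columns:
        raise ValueError(f"records need a {group_col!r} column")
    return {g: km_fit(sub) for g, sub in df.groupby(group_col, sort=True)}
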