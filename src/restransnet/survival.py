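"""Kaplan-Meier survival estimation and the log-rank test.

Wraps lifelines: product-limit curves with Brookmeyer-Crowley style median
confidence intervals (log(-log) transformed Greenwood variance, the lifelines
default), and the standard (O-E)^2/V chi-square log-rank comparison between
predicted PD-1 groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times

from .preprocess import SurvivalRecord


@dataclass
class KMCurve:
    times: np.ndarray               # event/censoring times on the step grid
    survival: np.ndarray            # S(t), non-increasing from 1
    at_risk: np.ndarray
    median: float                   # np.inf when not reached
    median_ci: tuple[float, float]  # 95% CI bounds (inf = not reached)

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "at_risk": self.at_risk})


@dataclass
class LogRankResult:
    statistic: float  # chi-square, 1 df
    p_value: float


def _to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, tuple) and len(records) == 2:
        return np.asarray(records[0], float), np.asarray(records[1], int)
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return times, events


def km_estimate(records: list[SurvivalRecord] | tuple[np.ndarray, np.ndarray],
                alpha: float = 0.05) -> KMCurve:
    """Product-limit estimator S(t) = prod(1 - d_i/n_i) with the deaths-
    before-censorings tie convention; median is the first time S(t) <= 0.5."""
    times, events = _to_arrays(records)
    if len(times) == 0:
        raise ValueError("no survival records")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, events)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy()
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return KMCurve(times=grid, survival=surv, at_risk=at_risk,
                   median=median, median_ci=(lo, hi))


def log_rank(group0, group1) -> LogRankResult:
    """Two-group log-rank chi-square over pooled event times."""
    t0, e0 = _to_arrays(group0)
    t1, e1 = _to_arrays(group1)
    res = _ll_logrank(t0, t1, event_observed_A=e0, event_observed_B=e1)
    return LogRankResult(statistic=float(res.test_statistic),
                         p_value=float(res.p_value))


def km_summary(times: np.ndarray, events: np.ndarray,
               groups: np.ndarray) -> dict:
    """Per-group KM medians with CIs plus the log-rank comparison, in the
    shape the evaluation CLI writes as JSON."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups, int)
    out: dict = {"groups": {}}
    for g in (0, 1):
        mask = groups == g
        if mask.sum() == 0:
            continue
        curve = km_estimate((times[mask], events[mask]))
        out["groups"][str(g)] = {
            "n": int(mask.sum()),
            "events": int(events[mask].sum()),
            "median": None if not curve.median_reached else curve.median,
            "median_ci": [None if not np.isfinite(v) else v
                          for v in curve.median_ci],
        }
    if len(out["groups"]) == 2:
        lr = log_rank((times[groups == 0], events[groups == 0]),
                      (times[groups == 1], events[groups == 1]))
        out["log_rank"] = {"chi_square": lr.statistic, "p": lr.p_value}
    return out
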