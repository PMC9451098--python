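"""Kaplan-Meier estimation and two-sample log-rank testing.

Thin wrappers around lifelines, exposing the estimator pieces the rest of the
package needs (product-limit curve, at-risk counts, chi-square log-rank).
Ties between events and censorings at the same time follow the standard
convention that events precede censorings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


@dataclass
class KMEstimate:
    """Product-limit survival estimate at the observed event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation S(t) (right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)
        return out


def kaplan_meier(times, events) -> KMEstimate:
    """Kaplan-Meier estimate from right-censored data.

    ``events`` is 1/True for an observed relapse, 0/False for censoring.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if len(times) == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    mask = tbl["observed"].to_numpy() > 0
    event_times = tbl.index.to_numpy()[mask]
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = tbl["at_risk"].to_numpy()[mask]
    return KMEstimate(event_times=event_times, survival=surv, at_risk=at_risk)


def log_rank(times1, events1, times2, events2) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square statistic, p-value)."""
    t1, t2 = np.asarray(times1, dtype=float), np.asarray(times2, dtype=float)
    e1, e2 = np.asarray(events1).astype(bool), np.asarray(events2).astype(bool)
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("both groups must be nonempty")
    if not e1.any() and not e2.any():
        return 0.0, 1.0
    res = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):
        return 0.0, 1.0
    return stat, p
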