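"""Kaplan–Meier estimation and log-rank comparison of patient groups.

Times are days from diagnosis; status is "died" (event) or "censored"
(alive with disease at last follow-up, treated as non-informative).  Ties at
an event time follow the discrete product-limit convention (deaths before
censorings at the same time).  Estimation and testing delegate to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .stats_core import TestResult


@dataclass
class SurvivalCurve:
    """Step survival estimate: event times, at-risk counts, Ŝ(t)."""

    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray
    all_censored: bool = False

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _encode(statuses) -> np.ndarray:
    out = []
    for s in statuses:
        if s in (1, True, "died", "event"):
            out.append(1)
        elif s in (0, False, "censored"):
            out.append(0)
        else:
            raise ValueError(f"invalid status {s!r}")
    return np.asarray(out, dtype=int)


def km_estimate(times, statuses) -> SurvivalCurve:
    """Product-limit estimator Ŝ(t) = Π_{t_i ≤ t} (1 − d_i / n_i)."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty survival input")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    e = _encode(statuses)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_["KM_estimate"]
    event_times = np.unique(t[e == 1])
    surv = np.array([float(sf.loc[:et].iloc[-1]) for et in event_times])
    n_at_risk = np.array([(t >= et).sum() for et in event_times])
    return SurvivalCurve(
        times=event_times,
        at_risk=n_at_risk,
        survival=surv,
        censor_times=np.sort(t[e == 0]),
        all_censored=bool((e == 0).all()),
    )


def logrank_test(groups: list[tuple]) -> TestResult:
    """Log-rank chi-square test over ≥2 groups of (times, statuses)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for gi, (t, s) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        if t.size == 0:
            raise ValueError(f"group {gi} has zero subjects")
        e = _encode(s)
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, gi))
    times = np.concatenate(times)
    events = np.concatenate(events)
    labels = np.concatenate(labels)
    if events.sum() == 0:
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(times, labels, events)
    return TestResult(statistic=float(res.test_statistic),
                      p_value=float(res.p_value),
                      method=f"logrank_{len(groups)}group")


def survival_by_group(meta: pd.DataFrame, groupby: str = "group") -> dict:
    """KM curves and the log-rank test for the metadata table's groups.

    Rows without time or status are dropped; returns per-group curves and
    the overall test (None when fewer than two usable groups)."""
    usable = meta.dropna(subset=["time_days", "status"])
    curves = {}
    groups = []
    for name, grp in usable.groupby(groupby):
        curves[name] = km_estimate(grp["time_days"], grp["status"])
        groups.append((grp["time_days"].to_numpy(dtype=float),
                       list(grp["status"])))
    test = logrank_test(groups) if len(groups) >= 2 else None
    return {"curves": curves, "test": test}


def curve_table(curve: SurvivalCurve) -> pd.DataFrame:
    return pd.DataFrame({
        "time": curve.times,
        "at_risk": curve.at_risk,
        "survival": curve.survival,
    })
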