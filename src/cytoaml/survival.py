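"""Kaplan-Meier estimation and log-rank comparison of patient groups.

Thin, typed wrappers around lifelines: the product-limit estimator per
prognostic group, median survival (first time the survival curve drops
to or below one half), and the two-group log-rank chi-square test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank_test

__all__ = [
    "SurvivalRecord",
    "KMEstimate",
    "LogrankResult",
    "km_estimate",
    "logrank_test",
    "compare_groups",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time in days (overall survival or time
    since first relapse, per the chosen origin), death-observed flag,
    and the prognostic group label."""

    patient_id: str
    time: float
    event: bool
    group: str

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"survival time must be > 0, got {self.time}")


@dataclass
class KMEstimate:
    """Product-limit survival curve for one group."""

    times: np.ndarray  # event/censoring times (step locations)
    survival: np.ndarray  # S(t) immediately after each time
    median: float  # nan if S never reaches 1/2
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function evaluation."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _to_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([int(r.event) for r in records])
    return t, e


def km_estimate(records: Sequence[SurvivalRecord]) -> KMEstimate:
    """Kaplan-Meier estimate with the conservative median convention:
    the median is the earliest time at which S(t) <= 1/2, NaN if the
    curve never reaches one half."""
    if len(records) == 0:
        raise ValueError("need at least one survival record")
    t, e = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    if math.isinf(median):
        median = math.nan
    return KMEstimate(
        times=times,
        survival=surv,
        median=median,
        n=len(records),
        n_events=int(e.sum()),
    )


@dataclass
class LogrankResult:
    statistic: float  # chi-square, 1 df
    p_value: float


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> LogrankResult:
    """Standard two-group log-rank test (chi-square with 1 df)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    ta, ea = _to_arrays(group_a)
    tb, eb = _to_arrays(group_b)
    if ea.sum() == 0 or eb.sum() == 0:
        warnings.warn("a group has zero observed events; log-rank power is limited")
    res = _ll_logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogrankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


def compare_groups(
    records: Sequence[SurvivalRecord],
) -> tuple[dict[str, KMEstimate], Optional[LogrankResult]]:
    """Per-group KM curves plus the log-rank test when exactly two
    groups are present (None otherwise)."""
    groups: dict[str, list[SurvivalRecord]] = {}
    for r in records:
        groups.setdefault(r.group, []).append(r)
    estimates = {g: km_estimate(rs) for g, rs in sorted(groups.items())}
    test = None
    if len(groups) == 2:
        (ga, gb) = sorted(groups)
        test = logrank_test(groups[ga], groups[gb])
    return estimates, test
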