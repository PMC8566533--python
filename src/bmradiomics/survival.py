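"""Patient-level survival comparison of predicted vs observed LC/LF cohorts.

A patient belongs to the LF cohort if any of their lesions has an LF
outcome (predicted at pre-treatment or adjudicated at follow-up); the two
cohorts are compared with Kaplan-Meier curves and a two-sample log-rank
test.  Estimation is delegated to ``lifelines``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogRankResult",
    "assign_patient_cohorts",
    "km_curve",
    "logrank_test",
    "compare_cohorts",
]


@dataclass
class SurvivalRecord:
    patient_id: str
    time: float  # months
    event: bool
    cohort: str  # "LC" | "LF"

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if self.cohort not in ("LC", "LF"):
            raise ValueError("cohort must be 'LC' or 'LF'")


@dataclass
class KMCurve:
    times: np.ndarray  # distinct event times (steps)
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size just before each event time
    median: float | None  # months; None if the curve stays above 0.5


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float


def assign_patient_cohorts(lesion_outcomes) -> dict[str, str]:
    """Map each patient to LF if any of their lesions is LF, else LC.

    ``lesion_outcomes`` is an iterable of ``(patient_id, outcome)`` pairs or
    a DataFrame with those columns.
    """
    if isinstance(lesion_outcomes, pd.DataFrame):
        pairs = lesion_outcomes[["patient_id", "outcome"]].itertuples(index=False)
    else:
        pairs = lesion_outcomes
    cohorts: dict[str, str] = {}
    for pid, outcome in pairs:
        if outcome not in ("LC", "LF"):
            raise ValueError(f"unknown outcome {outcome!r}")
        if cohorts.get(pid) != "LF":
            cohorts[pid] = "LF" if outcome == "LF" else "LC"
    return cohorts


def km_curve(records: list[SurvivalRecord] | pd.DataFrame) -> KMCurve:
    """Product-limit (Kaplan-Meier) survival curve.

    The reported ``times`` are the distinct event times; censored times only
    shrink the risk set.  The median is the smallest time with S(t) <= 0.5
    and ``None`` if the curve never reaches 0.5 (never extrapolated).
    """
    times, events = _to_arrays(records)
    if len(times) == 0:
        raise ValueError("no survival records")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    ev_times = np.sort(np.unique(times[events]))
    if ev_times.size:
        surv = kmf.survival_function_at_times(ev_times).to_numpy()
        ev_table = kmf.event_table
        at_risk = ev_table.loc[ev_times, "at_risk"].to_numpy()
    else:
        surv = np.array([])
        at_risk = np.array([])
    med = float(kmf.median_survival_time_)
    return KMCurve(
        times=ev_times.astype(float),
        survival=surv.astype(float),
        at_risk=at_risk.astype(float),
        median=None if np.isinf(med) else med,
    )


def _to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        return records["time"].to_numpy(dtype=float), records["event"].to_numpy(dtype=bool)
    return (
        np.array([r.time for r in records], dtype=float),
        np.array([r.event for r in records], dtype=bool),
    )


def logrank_test(group_a, group_b) -> LogRankResult:
    """Two-sample log-rank test (hypergeometric expected events, 1 df)."""
    ta, ea = _to_arrays(group_a)
    tb, eb = _to_arrays(group_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if not (ea.any() or eb.any()):
        raise ValueError("no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogRankResult(chi_square=float(res.test_statistic), p_value=float(res.p_value))


def compare_cohorts(records: list[SurvivalRecord]) -> dict:
    """KM curves and log-rank comparison of the LC and LF cohorts."""
    lc = [r for r in records if r.cohort == "LC"]
    lf = [r for r in records if r.cohort == "LF"]
    out: dict = {
        "n_lc": len(lc),
        "n_lf": len(lf),
        "km_lc": km_curve(lc) if lc else None,
        "km_lf": km_curve(lf) if lf else None,
    }
    if lc and lf:
        lr = logrank_test(lc, lf)
        out["logrank"] = lr
    return out
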