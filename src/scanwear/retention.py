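"""Day-state classification and retention survival analysis.

Each observed day is active or nonactive; nonactive days later followed by
an active day are temporary disengagement ("inactive"), while the terminal
nonactive run is the sustained "exit". The survival event is the first day
of that terminal run; participants still active through the 180-day horizon
(or whose exit starts at/after it) are censored at the horizon. Kaplan-Meier
estimation and log-rank comparisons are delegated to lifelines; median
confidence intervals come from inverting the log-log survival CI band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times, qth_survival_times

__all__ = [
    "SurvivalRecord",
    "KMSummary",
    "classify_states",
    "first_sustained_exit",
    "km_fit",
    "log_rank",
    "survival_records",
]

ACTIVE, INACTIVE, EXIT = "active", "inactive", "exit"


@dataclass(frozen=True)
class SurvivalRecord:
    participant_id: str
    modality: str
    time_days: int
    event: bool


@dataclass
class KMSummary:
    """Product-limit curve plus median / IQR / median-CI summaries."""

    curve: pd.DataFrame  # columns: time, survival, at_risk
    median: float  # NaN when not reached
    iqr: tuple  # (q75-survival time, q25-survival time); NaN when not reached
    median_ci: tuple  # 95% CI for the median, NaN bounds when not reached
    fitter: KaplanMeierFitter


def classify_states(active) -> np.ndarray:
    """Label each day active / inactive / exit.

    Nonactive days are exit only in the terminal run (no active day after
    them); every earlier nonactive day is inactive.
    """
    active = np.asarray(active, dtype=bool)
    if active.size == 0:
        raise ValueError("empty day series")
    states = np.where(active, ACTIVE, INACTIVE).astype(object)
    if active.any():
        last_active = int(np.nonzero(active)[0][-1])
        states[last_active + 1:] = EXIT
    else:
        states[:] = EXIT
    return states


def first_sustained_exit(
    active, horizon: int = 180, participant_id: str = "", modality: str = ""
) -> SurvivalRecord:
    """Derive the (time, event) pair from a day-activity series.

    The series is interpreted on the horizon grid: days beyond its end are
    nonactive (a participant who stops producing records has disengaged).
    The event time is the first day of the terminal exit run; an exit
    starting at or after ``horizon`` is censored at ``horizon``.
    """
    active = np.asarray(active, dtype=bool)
    if active.size == 0:
        raise ValueError("empty day series")
    within = active[:horizon]
    if within.any():
        exit_start = int(np.nonzero(within)[0][-1]) + 1
    else:
        exit_start = 0
    if exit_start < horizon:
        return SurvivalRecord(participant_id, modality, exit_start, True)
    return SurvivalRecord(participant_id, modality, horizon, False)


def survival_records(
    daily: pd.DataFrame,
    participants: pd.DataFrame,
    modality: str,
    threshold_hours: float = 6.0,
    horizon_days: int = 180,
) -> pd.DataFrame:
    """Per-participant survival table with strata columns attached."""
    from .engagement import active_series

    rows = []
    for _, part in participants.iterrows():
        pid = part["participant_id"]
        sub = daily[daily["participant_id"] == pid]
        if sub.empty:
            rec = SurvivalRecord(pid, modality, 0, True)  # never produced a record
        else:
            act = active_series(sub, modality, threshold_hours, horizon_days)
            rec = first_sustained_exit(act, horizon_days, pid, modality)
        rows.append(
            {
                "participant_id": pid,
                "modality": modality,
                "time_days": rec.time_days,
                "event": rec.event,
                "age_group": part.get("age_group"),
                "tp53_status": part.get("tp53_status"),
                "cancer_history": part.get("cancer_history"),
            }
        )
    return pd.DataFrame(rows)


def km_fit(records: pd.DataFrame, alpha: float = 0.05) -> KMSummary:
    """Product-limit estimator with median, IQR and median 95% CI."""
    if len(records) == 0:
        raise ValueError("no survival records")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(records["time_days"], event_observed=records["event"])
    sf = kmf.survival_function_.iloc[:, 0]
    times = sf.index.to_numpy(dtype=float)
    all_times = records["time_days"].to_numpy(dtype=float)
    curve = pd.DataFrame(
        {
            "time": times,
            "survival": sf.to_numpy(),
            "at_risk": [(all_times >= t).sum() for t in times],
        }
    )
    median = float(kmf.median_survival_time_)
    q75 = float(qth_survival_times(0.75, sf))  # first t with S(t) <= 0.75
    q25 = float(qth_survival_times(0.25, sf))
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    inf_to_nan = lambda x: float("nan") if np.isinf(x) else x
    return KMSummary(
        curve=curve,
        median=inf_to_nan(median),
        iqr=(inf_to_nan(q75), inf_to_nan(q25)),
        median_ci=(inf_to_nan(lo), inf_to_nan(hi)),
        fitter=kmf,
    )


def log_rank(records: pd.DataFrame, stratum: str):
    """k-sample log-rank test across the levels of ``stratum``.

    Returns (chi2, df, p). Every stratum level must be non-empty and at
    least one event must be observed overall.
    """
    groups = records[stratum]
    counts = groups.value_counts()
    if (counts == 0).any() or len(counts) < 2:
        raise ValueError(f"log-rank needs >=2 non-empty strata for {stratum!r}")
    if not records["event"].any():
        raise ValueError("log-rank needs at least one event")
    res = multivariate_logrank_test(records["time_days"], groups, records["event"])
    return float(res.test_statistic), int(len(counts) - 1), float(res.p_value)
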