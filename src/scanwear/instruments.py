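"""Questionnaire scoring, the PHQ-9 item-9 alert rule, stress-frequency and
rolling-score matrices, and per-instrument group comparisons.

Scoring rules are those of the published instruments: PHQ-9 (9 items, 0-3),
GAD-7 (7 items, 0-3), PSS-4 (4 items 0-4 with items 2 and 3 reverse-scored),
PROMIS Sleep-Related Impairment short form (8 items, 1-5, reported as the
raw sum). Incomplete responses are excluded, never prorated. Group tests
aggregate to one mean total per participant first, so n is participants,
not responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engagement import WelchResult, welch_t

__all__ = [
    "INSTRUMENT_SPECS",
    "AlertEvent",
    "score",
    "score_table",
    "check_alert",
    "alert_log",
    "stress_frequency",
    "rolling_score_matrix",
    "group_compare",
]

#: instrument -> (n_items, item_min, item_max, reverse-scored 1-based items)
INSTRUMENT_SPECS = {
    "PHQ9": (9, 0, 3, ()),
    "GAD7": (7, 0, 3, ()),
    "PSS4": (4, 0, 4, (2, 3)),
    "PROMIS_SRI": (8, 1, 5, ()),
}


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class AlertEvent:
    participant_id: str
    day_index: int
    item9_value: int


def score(instrument: str, items) -> int:
    """Total score with reverse-scoring applied where the instrument requires it."""
    if instrument not in INSTRUMENT_SPECS:
        raise ScoringError(f"unknown instrument {instrument!r}")
    n_items, lo, hi, reverse = INSTRUMENT_SPECS[instrument]
    items = list(items)
    if len(items) != n_items:
        raise ScoringError(f"{instrument} expects {n_items} items, got {len(items)}")
    total = 0
    for idx, v in enumerate(items, start=1):
        if not (np.isfinite(v) and int(v) == v and lo <= v <= hi):
            raise ScoringError(f"{instrument} item {idx} out of range [{lo},{hi}]: {v!r}")
        total += (hi - int(v)) if idx in reverse else int(v)
    return total


def check_alert(participant_id: str, day_index: int, items) -> AlertEvent | None:
    """PHQ-9 self-harm alert: any positive response on item 9."""
    item9 = int(items[8])
    if item9 >= 1:
        return AlertEvent(participant_id, int(day_index), item9)
    return None


def score_table(instruments: pd.DataFrame) -> pd.DataFrame:
    """Score every complete response in the long-format table.

    Returns one row per (participant, day, instrument) with the total;
    incomplete or out-of-range responses are dropped and listed in the
    ``excluded`` attribute of the result.
    """
    rows, excluded = [], []
    grouped = instruments.groupby(["participant_id", "day_index", "instrument"], sort=True)
    for (pid, day, inst), grp in grouped:
        items = grp.sort_values("item_index")["value"].to_list()
        try:
            total = score(inst, items)
        except ScoringError as err:
            excluded.append({"participant_id": pid, "day_index": day,
                             "instrument": inst, "reason": str(err)})
            continue
        rows.append({"participant_id": pid, "day_index": int(day),
                     "instrument": inst, "total": total})
    out = pd.DataFrame(rows, columns=["participant_id", "day_index", "instrument", "total"])
    out.attrs["excluded"] = excluded
    return out


def alert_log(instruments: pd.DataFrame) -> pd.DataFrame:
    """Audit-complete PHQ-9 item-9 alert table: exactly one row per response
    with item 9 >= 1."""
    phq = instruments[instruments["instrument"] == "PHQ9"]
    rows = []
    for (pid, day), grp in phq.groupby(["participant_id", "day_index"], sort=True):
        items = grp.sort_values("item_index")["value"].to_list()
        if len(items) != 9:
            continue
        event = check_alert(pid, day, items)
        if event is not None:
            rows.append({"participant_id": event.participant_id,
                         "day_index": event.day_index,
                         "item9_value": event.item9_value})
    return pd.DataFrame(rows, columns=["participant_id", "day_index", "item9_value"])


def stress_frequency(daily: pd.DataFrame, max_level: int = 3) -> float:
    """Share of completed daily surveys reporting the top stress level."""
    completed = daily[daily["survey_completed"].astype(bool)]
    if len(completed) == 0:
        return float("nan")
    return float((completed["stress_level"] == max_level).mean())


def rolling_score_matrix(
    scores: pd.DataFrame, instrument: str, window_days: int = 28, horizon_days: int = 180
) -> pd.DataFrame:
    """Participant x day matrix of centered rolling-mean totals.

    A cell is the mean of the participant's totals within ``window_days``
    (centered) around that day; days with no response in-window are NaN.
    """
    half = window_days // 2
    days = np.arange(horizon_days)
    sub = scores[scores["instrument"] == instrument]
    mat = {}
    for pid, grp in sub.groupby("participant_id", sort=True):
        obs_days = grp["day_index"].to_numpy()
        totals = grp["total"].to_numpy(dtype=float)
        row = np.full(horizon_days, np.nan)
        for d in days:
            mask = (obs_days >= d - half) & (obs_days <= d + half)
            if mask.any():
                row[d] = totals[mask].mean()
        mat[pid] = row
    return pd.DataFrame(mat, index=days).T


def group_compare(
    scores: pd.DataFrame,
    participants: pd.DataFrame,
    stratum: str = "age_group",
) -> pd.DataFrame:
    """Welch comparison of per-participant mean totals across two stratum levels.

    Levels with fewer than 2 participants yield a flagged row with no test.
    """
    merged = scores.merge(participants[["participant_id", stratum]], on="participant_id")
    rows = []
    for inst, grp in merged.groupby("instrument", sort=True):
        per_part = grp.groupby(["participant_id", stratum], observed=True)["total"].mean().reset_index()
        levels = sorted(per_part[stratum].astype(str).unique())
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                a = per_part.loc[per_part[stratum].astype(str) == levels[i], "total"]
                b = per_part.loc[per_part[stratum].astype(str) == levels[j], "total"]
                row = {"instrument": inst, "stratum": stratum,
                       "level_a": levels[i], "level_b": levels[j],
                       "n_a": len(a), "n_b": len(b)}
                if len(a) < 2 or len(b) < 2:
                    row.update({"t": np.nan, "df": np.nan, "p": np.nan, "flag": "n<2"})
                else:
                    res: WelchResult = welch_t(a, b)
                    row.update({"t": res.t_statistic, "df": res.df, "p": res.p_value,
                                "mean_a": res.group_means[0], "mean_b": res.group_means[1],
                                "flag": ""})
                rows.append(row)
    return pd.DataFrame(rows)
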