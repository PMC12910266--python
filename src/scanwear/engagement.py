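"""Engagement metrics: daily activity flags, rates, smoothing, watch-survey
coupling, Welch group comparisons and the wear-time summary table.

A watch day is *active* when valid wear reaches the threshold (default 6 h,
boundary inclusive); a survey day is active when the daily stress measure
was completed. Rates are computed over each participant's observed span
(first through last recorded day, capped at the follow-up horizon); days
with no record count as nonactive for rates but as missing for smoothing so
that gaps do not inject artificial zeros into the periodogram input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WelchResult",
    "daily_watch_active",
    "active_series",
    "engagement_rate",
    "rolling_smooth",
    "coupling",
    "welch_t",
    "wear_time_summary",
]


class DataError(ValueError):
    """Raised for records that violate the data contract."""


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    df: float
    p_value: float
    group_means: tuple
    group_sds: tuple
    group_ns: tuple


def daily_watch_active(valid_wear_minutes, threshold_hours: float = 6.0):
    """True where daily valid wear meets the threshold (inclusive)."""
    minutes = np.asarray(valid_wear_minutes)
    if np.any(minutes < 0):
        raise DataError("valid_wear_minutes must be non-negative")
    if np.any(minutes > 1440):
        raise DataError("valid_wear_minutes cannot exceed 1440")
    return minutes >= threshold_hours * 60.0


def active_series(
    daily: pd.DataFrame,
    modality: str,
    threshold_hours: float = 6.0,
    horizon_days: int = 180,
    span: str = "observed",
) -> pd.Series:
    """Per-day boolean activity for one participant's records.

    The index is a contiguous day grid from 0 through the end of the span
    (``observed``: last recorded day; ``horizon``: horizon_days - 1); days
    without a record are nonactive.
    """
    if daily.empty:
        raise DataError("no daily records for participant")
    last = int(daily["day_index"].max())
    end = horizon_days - 1 if span == "horizon" else min(last, horizon_days - 1)
    grid = np.arange(end + 1)
    out = pd.Series(False, index=grid, name=modality)
    sub = daily[daily["day_index"] <= end]
    if modality == "watch":
        flags = daily_watch_active(sub["valid_wear_minutes"], threshold_hours)
    elif modality == "survey":
        flags = sub["survey_completed"].fillna(False).astype(bool).to_numpy()
    else:
        raise ValueError(f"unknown modality {modality!r}")
    out.loc[sub["day_index"].to_numpy()] = flags
    return out


def engagement_rate(active: pd.Series) -> float:
    """Fraction of observed days that are active."""
    if len(active) == 0:
        raise DataError("empty engagement series")
    return float(np.asarray(active, dtype=float).mean())


def rolling_smooth(active, window: int = 7) -> pd.Series:
    """Centered rolling mean; edge windows truncate to the available span and
    missing values are excluded from (not imputed into) each window mean."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    s = pd.Series(np.asarray(active, dtype=float))
    s.index = getattr(active, "index", s.index)
    return s.rolling(window=window, center=True, min_periods=1).mean()


def coupling(watch_smoothed: pd.Series, survey_smoothed: pd.Series) -> float:
    """Pearson correlation of the two smoothed series on their day overlap.

    Returns NaN (with a warning) when either series is constant on the
    overlap — an undefined correlation is reported as missing, never as 0.
    """
    a, b = watch_smoothed.align(survey_smoothed, join="inner")
    mask = a.notna() & b.notna()
    a, b = a[mask], b[mask]
    if len(a) < 3:
        raise DataError("need at least 3 overlapping days for coupling")
    if np.ptp(a.to_numpy()) == 0 or np.ptp(b.to_numpy()) == 0:
        warnings.warn("constant smoothed series: coupling undefined", RuntimeWarning)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def welch_t(a, b) -> WelchResult:
    """Two-sample Welch t test (unequal variances, Satterthwaite df, 2-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise DataError("each group needs at least 2 finite observations")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        # both groups constant: no evidence either way
        return WelchResult(0.0, float(na + nb - 2), 1.0, (ma, mb),
                           (0.0, 0.0), (na, nb))
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(
        float(t), float(df), float(p),
        (float(ma), float(mb)),
        (float(np.sqrt(va)), float(np.sqrt(vb))),
        (na, nb),
    )


def wear_time_summary(
    daily: pd.DataFrame,
    participants: pd.DataFrame,
    threshold_hours: float = 6.0,
    stratum: str = "age_group",
    horizon_days: int = 180,
) -> pd.DataFrame:
    """Stratified wear-metric table (Table-1 analog).

    Per stratum: mean (SD) across participants of percent days worn, and of
    total / sleep / awake hours per worn day, where a "worn day" meets the
    wear threshold. Empty strata yield a row of NaNs rather than vanishing.
    """
    rows = []
    merged = daily.merge(
        participants[["participant_id", stratum]], on="participant_id", how="left"
    )
    for level in participants[stratum].unique():
        pids = participants.loc[participants[stratum] == level, "participant_id"]
        per_part = []
        for pid in pids:
            sub = merged[(merged["participant_id"] == pid)]
            if sub.empty:
                continue
            act = active_series(sub, "watch", threshold_hours, horizon_days)
            worn = sub[daily_watch_active(sub["valid_wear_minutes"], threshold_hours)]
            per_part.append(
                {
                    "pct_days_worn": 100.0 * engagement_rate(act),
                    "days_worn": float(len(worn)),
                    "total_h": worn["valid_wear_minutes"].mean() / 60.0,
                    "sleep_h": worn["sleep_wear_minutes"].mean() / 60.0,
                    "awake_h": worn["awake_wear_minutes"].mean() / 60.0,
                }
            )
        stats_df = pd.DataFrame(per_part)
        row = {"stratum": stratum, "level": level, "n": len(per_part)}
        for metric in ("pct_days_worn", "days_worn", "total_h", "sleep_h", "awake_h"):
            if len(stats_df):
                row[f"{metric}_mean"] = float(stats_df[metric].mean())
                row[f"{metric}_sd"] = float(stats_df[metric].std(ddof=1)) if len(stats_df) > 1 else float("nan")
            else:
                row[f"{metric}_mean"] = float("nan")
                row[f"{metric}_sd"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
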