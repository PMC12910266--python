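"""Synthetic Li-Fraumeni-like digital-health cohort generator.

Every quantity the analysis stages estimate is *planted* here with a known
value taken from :class:`~scanwear.config.CohortConfig`: age-group adherence
means, adherence decay and a biweekly check-in cycle, absorbing dropout whose
geometric hazard implies a target retention median, watch/survey coupling,
instrument-score group differences, a PHQ-9 item-9 alert rate, and smooth
pre-scan physiological signatures. The generator is the ground-truth oracle
for the pipeline's recovery tests; it does not attempt realistic circadian
physiology or raw-sensor artifacts.

All randomness flows from ``config.seed`` through a :class:`numpy.random.
SeedSequence` spawn tree, so a fixed seed reproduces the cohort byte for
byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import PHYSIO_CHANNELS, CohortConfig, ConfigurationError

__all__ = [
    "SimulatedCohort",
    "generate_cohort",
    "adherence_profile",
    "simulate_wear",
    "simulate_surveys",
    "simulate_scans",
    "simulate_physio",
    "simulate_instruments",
    "simulate_cohort",
    "write_cohort",
]

_ENROLLMENT_START = date(2022, 1, 1)
_ENROLLMENT_SPAN_DAYS = 150  # rolling recruitment window (Jan-Jun)

# per-channel signed effect amplitude at unit config amplitude (log scale for
# EDA/HRV) and noise SD at unit config noise; HRV and skin temperature drop
# under anticipatory stress, the others rise
_EFFECT_SCALE = {
    "eda": 0.5,
    "heart_rate": 6.0,
    "hrv": -0.4,
    "resp_rate": 2.0,
    "temperature": -0.5,
}
_NOISE_SCALE = {
    "eda": 0.30,
    "heart_rate": 5.0,
    "hrv": 0.25,
    "resp_rate": 1.5,
    "temperature": 0.4,
}

_INSTRUMENTS = {
    # instrument: (n_items, item_min, item_max)
    "PHQ9": (9, 0, 3),
    "GAD7": (7, 0, 3),
    "PSS4": (4, 0, 4),
    "PROMIS_SRI": (8, 1, 5),
}


@dataclass
class SimulatedCohort:
    """All tables of one simulated cohort plus the config that planted them."""

    participants: pd.DataFrame
    daily: pd.DataFrame
    scans: pd.DataFrame
    physio: pd.DataFrame
    instruments: pd.DataFrame
    config: CohortConfig


def _age_params(config: CohortConfig, age_group: str) -> dict:
    if age_group == "child":
        return {
            "wear_base": config.wear_adherence_mean_child,
            "dropout": config.dropout_hazard_child,
            "wear_hours_mean": config.wear_hours_mean_child,
            "wear_hours_sd": config.wear_hours_sd_child,
            "survey_base": config.survey_completion_mean_child,
            "stress_p3": config.stress_p3_child,
            "phq9": (config.phq9_mean_child, config.phq9_sd_child),
            "promis": (config.promis_mean_child, config.promis_sd_child),
        }
    return {
        "wear_base": config.wear_adherence_mean_adult,
        "dropout": config.dropout_hazard_adult,
        "wear_hours_mean": config.wear_hours_mean_adult,
        "wear_hours_sd": config.wear_hours_sd_adult,
        "survey_base": config.survey_completion_mean_adult,
        "stress_p3": config.stress_p3_adult,
        "phq9": (config.phq9_mean_adult, config.phq9_sd_adult),
        "promis": (config.promis_mean_adult, config.promis_sd_adult),
    }


def generate_cohort(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the participant table: strata proportions match the config within
    integer rounding, assignment within stratum is randomized."""
    if config.n_children < 0 or config.n_adults < 0:
        raise ConfigurationError("participant counts must be non-negative")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    rows = []
    n_total = config.n_children + config.n_adults
    for i in range(n_total):
        is_child = i < config.n_children
        rows.append(
            {
                "participant_id": f"P{i:03d}",
                "age_group": "child" if is_child else "adult",
                "age_years": float(rng.uniform(8, 18) if is_child else rng.uniform(23, 68)),
                "enrollment_day": (
                    _ENROLLMENT_START
                    + timedelta(days=int(rng.integers(0, _ENROLLMENT_SPAN_DAYS + 1)))
                ).isoformat(),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["participant_id", "age_group", "age_years", "enrollment_day"],
    )
    if df.empty:
        df["tp53_status"] = pd.Series(dtype=object)
        df["cancer_history"] = pd.Series(dtype=bool)
        return df

    tp53 = np.full(n_total, "wt", dtype=object)
    cancer = np.zeros(n_total, dtype=bool)
    child_idx = np.arange(config.n_children)
    adult_idx = np.arange(config.n_children, n_total)
    if config.all_children_carriers:
        tp53[child_idx] = "mut"
    elif len(child_idx):
        k = round(len(child_idx) * config.prop_tp53_mut_adults)
        tp53[rng.permutation(child_idx)[:k]] = "mut"
    if len(adult_idx):
        k = round(len(adult_idx) * config.prop_tp53_mut_adults)
        tp53[rng.permutation(adult_idx)[:k]] = "mut"
    for idx, prop in ((child_idx, config.prop_cancer_history_child),
                      (adult_idx, config.prop_cancer_history_adult)):
        if len(idx):
            k = round(len(idx) * prop)
            cancer[rng.permutation(idx)[:k]] = True
    df["tp53_status"] = tp53
    df["cancer_history"] = cancer
    return df[["participant_id", "age_group", "age_years", "tp53_status",
               "cancer_history", "enrollment_day"]]


def adherence_profile(config: CohortConfig, base: float) -> np.ndarray:
    """Planted daily activity probability over the horizon.

    ``base`` is the *mean* adherence over the horizon: an exponential decay
    (half-life ``adherence_decay_halflife_days``) multiplied by a sinusoid of
    period ``checkin_period_days`` gives the shape, and the shape is scaled —
    accounting for clipping to [0, 1] — so that the clipped profile's mean
    equals ``base`` exactly. This keeps the planted group adherence means
    recoverable even when the early-follow-up peak saturates at 1.
    """
    if base <= 0:
        return np.zeros(config.horizon_days)
    days = np.arange(config.horizon_days, dtype=float)
    if np.isfinite(config.adherence_decay_halflife_days):
        decay = np.exp(-np.log(2.0) * days / config.adherence_decay_halflife_days)
    else:
        decay = np.ones_like(days)
    cycle = 1.0 + config.checkin_amplitude * np.sin(
        2.0 * np.pi * days / config.checkin_period_days
    )
    shape = decay * cycle
    shape = shape / shape.mean()
    target = min(base, 1.0)
    lo, hi = 0.0, 1.0
    while np.clip(hi * shape, 0.0, 1.0).mean() < target and hi < 1e9:
        hi *= 2.0
    for _ in range(80):  # bisection on the scale of the clipped profile
        mid = 0.5 * (lo + hi)
        if np.clip(mid * shape, 0.0, 1.0).mean() < target:
            lo = mid
        else:
            hi = mid
    return np.clip(hi * shape, 0.0, 1.0)


def _on_study_mask(config: CohortConfig, hazard: float, rng: np.random.Generator) -> np.ndarray:
    """Absorbing dropout (optionally with re-entry): True while the
    participant produces records."""
    n = config.horizon_days
    if hazard <= 0 and config.reentry_prob <= 0:
        return np.ones(n, dtype=bool)
    if config.reentry_prob <= 0:
        dropout_day = rng.geometric(hazard) - 1  # support {0, 1, ...}
        return np.arange(n) < dropout_day
    on = np.ones(n, dtype=bool)
    state = True
    for day in range(n):
        if state and rng.random() < hazard:
            state = False
        elif not state and config.reentry_prob > 0 and rng.random() < config.reentry_prob:
            state = True
        on[day] = state
    return on


def simulate_wear(
    participant: pd.Series, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Daily valid wear minutes with sleep/awake split, truncated at dropout.

    Valid minutes are post-artifact-exclusion by contract (improper-wear
    detection is upstream of this data model). Worn days draw total hours
    from the age group's truncated normal; non-worn days are zero-inflated
    sub-threshold wear.
    """
    p = _age_params(config, participant["age_group"])
    probs = adherence_profile(config, p["wear_base"])
    on = _on_study_mask(config, p["dropout"], rng)
    days = np.nonzero(on)[0]  # absorbing dropout => a prefix; re-entry may leave gaps

    worn = rng.random(len(days)) < probs[days]
    hours = np.clip(rng.normal(p["wear_hours_mean"], p["wear_hours_sd"], len(days)), 6.0, 24.0)
    minutes = np.rint(hours * 60).astype(int)
    low = np.where(rng.random(len(days)) < 0.5, 0, rng.integers(1, 360, len(days)))
    valid = np.where(worn, minutes, low)
    valid = np.clip(valid, 0, 1440)

    frac = np.clip(rng.normal(config.sleep_fraction, 0.05, len(days)), 0.0, 1.0)
    sleep = np.minimum(np.rint(valid * frac).astype(int), 480)  # 23:00-07:00 window
    return pd.DataFrame(
        {
            "participant_id": participant["participant_id"],
            "day_index": days,
            "valid_wear_minutes": valid,
            "sleep_wear_minutes": sleep,
            "awake_wear_minutes": valid - sleep,
        }
    )


def simulate_surveys(
    participant: pd.Series,
    wear: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
    watch_threshold_minutes: int = 360,
) -> pd.DataFrame:
    """Daily stress-survey completion coupled to same-day watch activity.

    Completion probability on day ``d`` is ``p_s(d) + c (w_d - p_w(d))``
    (clipped to [0, 1]), where ``w_d`` is the day's watch-active indicator,
    ``p_w`` its planted probability and ``c`` the coupling weight: the
    deviation term has zero mean, so the survey marginal stays at its
    planted profile while completion covaries with watch wear. Completed
    days carry an ordinal stress level 0-3 with the configured mass on
    level 3 ("very stressed").
    """
    p = _age_params(config, participant["age_group"])
    probs = adherence_profile(config, p["survey_base"])
    watch_probs = adherence_profile(config, p["wear_base"])
    days = wear["day_index"].to_numpy()
    watch_active = (wear["valid_wear_minutes"].to_numpy() >= watch_threshold_minutes).astype(float)
    c = config.survey_watch_coupling
    p_complete = np.clip(probs[days] + c * (watch_active - watch_probs[days]), 0.0, 1.0)
    completed = rng.random(len(days)) < p_complete

    p3 = p["stress_p3"]
    rest = np.array([0.40, 0.35, 0.25]) * (1.0 - p3)
    stress = rng.choice(4, size=len(days), p=[rest[0], rest[1], rest[2], p3])
    stress_col = np.where(completed, stress.astype(float), np.nan)
    return pd.DataFrame(
        {
            "participant_id": participant["participant_id"],
            "day_index": days,
            "survey_completed": completed,
            "stress_level": stress_col,
        }
    )


def simulate_scans(
    participant: pd.Series, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Surveillance-scan events (MRI/ultrasound), 0-2 per participant."""
    cols = ["participant_id", "scan_id", "scan_day", "modality"]
    if rng.random() >= config.prop_with_scans or config.horizon_days < 60:
        return pd.DataFrame(columns=cols)
    two = rng.random() < config.prop_two_scans
    latest_first = config.horizon_days - 1
    if two:
        latest_first = max(45, config.horizon_days - config.scan_interval_days - 1)
    first = int(rng.integers(40, max(41, latest_first)))
    scan_days = [first]
    if two and first + config.scan_interval_days < config.horizon_days:
        scan_days.append(first + config.scan_interval_days)
    rows = []
    for j, d in enumerate(scan_days):
        rows.append(
            {
                "participant_id": participant["participant_id"],
                "scan_id": f"{participant['participant_id']}_S{j}",
                "scan_day": d,
                "modality": rng.choice(["MRI", "ultrasound", "other"], p=[0.6, 0.3, 0.1]),
            }
        )
    return pd.DataFrame(rows, columns=cols)


def prescan_effect(
    time_to_scan_min: np.ndarray, shape: str, amplitude: float, window_minutes: float
) -> np.ndarray:
    """Planted smooth effect as a function of minutes-to-scan.

    ``u = 1 - t/window`` rises from 0 at the window edge to 1 at the scan;
    the effect is ``amplitude * g(u)`` inside the window and 0 outside.
    This is the ground truth the additive-model stage must recover.
    """
    u = 1.0 - np.asarray(time_to_scan_min, dtype=float) / window_minutes
    inside = (u >= 0) & (u <= 1)
    u = np.clip(u, 0.0, 1.0)
    if shape == "flat":
        g = np.zeros_like(u)
    elif shape == "linear":
        g = u
    elif shape == "quadratic":
        g = u**2
    elif shape == "sigmoid":
        g = 1.0 / (1.0 + np.exp(-10.0 * (u - 0.5)))
    else:  # pragma: no cover - validated in config
        raise ValueError(f"unknown shape {shape!r}")
    return np.where(inside, amplitude * g, 0.0)


def simulate_physio(
    participant: pd.Series,
    scans: pd.DataFrame,
    wear: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Minute-level physiological samples around surveillance scans.

    Samples exist only for worn minutes (a contiguous block per day whose
    length is the day's valid wear), and only within ``physio_margin_days``
    before a scan — wide enough for both the wear-eligibility look-back and
    the modeling window. EDA and HRV are generated on the log scale so they
    stay strictly positive and are lognormal at baseline; pre-scan effects
    from overlapping windows sum. Each value is independently missing with
    ``missing_rate``, inflated by ``prescan_missing_boost`` inside the
    modeling window (missing-not-at-random by construction).
    """
    cols = ["participant_id", "timestamp_min"] + list(PHYSIO_CHANNELS)
    if scans.empty or wear.empty:
        return pd.DataFrame(columns=cols)

    baselines = {
        "eda": float(rng.lognormal(0.0, 0.4)),
        "heart_rate": float(rng.normal(70.0, 8.0)),
        "hrv": float(rng.lognormal(np.log(50.0), 0.3)),
        "resp_rate": float(rng.normal(14.0, 2.0)),
        "temperature": float(rng.normal(33.0, 0.8)),
    }
    scan_minutes = scans["scan_day"].to_numpy() * 1440  # midnight of scan day
    window_min = config.prescan_window_days * 1440

    keep = np.zeros(len(wear), dtype=bool)
    day_idx = wear["day_index"].to_numpy()
    for sd in scans["scan_day"].to_numpy():
        keep |= (day_idx >= sd - config.physio_margin_days) & (day_idx < sd)
    wear_kept = wear.loc[keep]

    ts_blocks = []
    for day, minutes in zip(wear_kept["day_index"], wear_kept["valid_wear_minutes"]):
        m = int(minutes)
        if m <= 0:
            continue
        start = int(rng.integers(0, 1440 - m + 1))
        ts_blocks.append(day * 1440 + start + np.arange(m))
    if not ts_blocks:
        return pd.DataFrame(columns=cols)
    ts = np.concatenate(ts_blocks)

    n = len(ts)
    in_window = np.zeros(n, dtype=bool)
    effects = {ch: np.zeros(n) for ch in PHYSIO_CHANNELS}
    for sm in scan_minutes:
        tts = sm - ts.astype(float)
        mask = (tts > 0) & (tts <= window_min)
        in_window |= mask
        for ch in PHYSIO_CHANNELS:
            amp = _EFFECT_SCALE[ch] * config.prescan_effect_amplitude
            effects[ch] += prescan_effect(tts, config.prescan_shapes[ch], amp, window_min)

    data = {"participant_id": participant["participant_id"], "timestamp_min": ts}
    p_missing = np.clip(
        config.missing_rate + config.prescan_missing_boost * in_window, 0.0, 1.0
    )
    for ch in PHYSIO_CHANNELS:
        noise = rng.normal(0.0, _NOISE_SCALE[ch] * config.physio_noise_sd, n)
        if ch in ("eda", "hrv"):
            values = np.exp(np.log(baselines[ch]) + effects[ch] + noise)
        else:
            values = baselines[ch] + effects[ch] + noise
        values = np.where(rng.random(n) < p_missing, np.nan, values)
        data[ch] = values
    return pd.DataFrame(data, columns=cols)


from functools import lru_cache


@lru_cache(maxsize=256)
def _censored_normal_mu(target: float, sd: float, lo: float, hi: float) -> float:
    """Latent normal mean whose [lo, hi]-censored expectation equals
    ``target`` (clipping draws to the instrument range raises the realized
    mean above the latent one, so the latent mean is solved for)."""
    from scipy import stats as _stats

    def censored_mean(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return (
            lo * _stats.norm.cdf(a)
            + hi * _stats.norm.sf(b)
            + mu * (_stats.norm.cdf(b) - _stats.norm.cdf(a))
            + sd * (_stats.norm.pdf(a) - _stats.norm.pdf(b))
        )

    lo_mu, hi_mu = lo - 6 * sd, hi + 6 * sd
    for _ in range(80):
        mid = 0.5 * (lo_mu + hi_mu)
        if censored_mean(mid) < target:
            lo_mu = mid
        else:
            hi_mu = mid
    return 0.5 * (lo_mu + hi_mu)


def _allocate_items(
    total: int, n_items: int, lo: int, hi: int, rng: np.random.Generator
) -> np.ndarray:
    """Spread ``total`` over ``n_items`` items each bounded to [lo, hi]."""
    items = np.full(n_items, lo)
    budget = int(np.clip(total, n_items * lo, n_items * hi)) - n_items * lo
    while budget > 0:
        open_idx = np.nonzero(items < hi)[0]
        items[rng.choice(open_idx)] += 1
        budget -= 1
    return items


def simulate_instruments(
    participant: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator,
    last_day: int | None = None,
) -> pd.DataFrame:
    """Biweekly instrument batteries (PHQ-9, GAD-7, PSS-4, PROMIS SRI).

    Totals are truncated-normal draws around the planted group means; item
    responses allocate the total across items. PHQ-9 item 9 (self-harm) is
    zero except for "alerter" participants (drawn with ``alert_item9_prob``),
    who get at least one positive item-9 response.
    """
    if last_day is None:
        last_day = config.horizon_days - 1
    p = _age_params(config, participant["age_group"])
    means = {
        "PHQ9": p["phq9"],
        "GAD7": (config.gad7_mean, config.gad7_sd),
        "PSS4": (config.pss4_mean, config.pss4_sd),
        "PROMIS_SRI": p["promis"],
    }
    alerter = rng.random() < config.alert_item9_prob
    days = list(range(0, last_day + 1, config.instrument_period_days))
    alert_day = days[int(rng.integers(0, len(days)))] if (alerter and days) else None

    # latent means adjusted so the range-censored totals hit the planted means
    bounds = {
        inst: ((8 * lo, 8 * hi) if inst == "PHQ9" else (n * lo, n * hi))
        for inst, (n, lo, hi) in _INSTRUMENTS.items()
    }
    latent_mu = {
        inst: _censored_normal_mu(means[inst][0], means[inst][1], *bounds[inst])
        for inst in _INSTRUMENTS
    }

    rows = []
    for day in days:
        for instrument, (n_items, lo, hi) in _INSTRUMENTS.items():
            mu, sd = latent_mu[instrument], means[instrument][1]
            lo_t, hi_t = bounds[instrument]
            total = int(np.rint(np.clip(rng.normal(mu, sd), lo_t, hi_t)))
            if instrument == "PHQ9":
                # item 9 is controlled separately; spread the total over items 1-8
                items8 = _allocate_items(total, 8, 0, 3, rng)
                item9 = 0
                if alerter and day == alert_day:
                    item9 = int(rng.integers(1, 4))
                items = np.concatenate([items8, [item9]])
            else:
                items = _allocate_items(total, n_items, lo, hi, rng)
            for j, v in enumerate(items):
                rows.append(
                    {
                        "participant_id": participant["participant_id"],
                        "day_index": day,
                        "instrument": instrument,
                        "item_index": j + 1,
                        "value": int(v),
                    }
                )
    return pd.DataFrame(
        rows, columns=["participant_id", "day_index", "instrument", "item_index", "value"]
    )


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Run the full generator: one seed, five tables, byte-identical reruns."""
    root = np.random.SeedSequence(config.seed)
    n_total = config.n_children + config.n_adults
    streams = root.spawn(n_total + 1)
    participants = generate_cohort(config, np.random.default_rng(streams[0]))

    daily_parts, scan_parts, physio_parts, instr_parts = [], [], [], []
    for i, (_, part) in enumerate(participants.iterrows()):
        rng = np.random.default_rng(streams[i + 1])
        wear = simulate_wear(part, config, rng)
        surveys = simulate_surveys(part, wear, config, rng)
        scans = simulate_scans(part, config, rng)
        physio = simulate_physio(part, scans, wear, config, rng)
        last_day = int(wear["day_index"].max()) if len(wear) else 0
        instruments = simulate_instruments(part, config, rng, last_day=last_day)
        daily_parts.append(wear.merge(surveys, on=["participant_id", "day_index"]))
        scan_parts.append(scans)
        physio_parts.append(physio)
        instr_parts.append(instruments)

    def _concat(parts, columns):
        parts = [p for p in parts if len(p)]
        if not parts:
            return pd.DataFrame(columns=columns)
        return pd.concat(parts, ignore_index=True)

    daily = _concat(
        daily_parts,
        ["participant_id", "day_index", "valid_wear_minutes", "sleep_wear_minutes",
         "awake_wear_minutes", "survey_completed", "stress_level"],
    )
    scans = _concat(scan_parts, ["participant_id", "scan_id", "scan_day", "modality"])
    physio = _concat(physio_parts, ["participant_id", "timestamp_min", *PHYSIO_CHANNELS])
    instruments = _concat(
        instr_parts, ["participant_id", "day_index", "instrument", "item_index", "value"]
    )
    return SimulatedCohort(participants, daily, scans, physio, instruments, config)


def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write the five delimited tables plus the config sidecar; returns paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    tables = {
        "participants.csv": cohort.participants,
        "daily.csv": cohort.daily,
        "scans.csv": cohort.scans,
        "physio.csv": cohort.physio,
        "instruments.csv": cohort.instruments,
    }
    for name, df in tables.items():
        path = os.path.join(outdir, name)
        df.to_csv(path, index=False, float_format="%.6g")
        paths[name] = path
    sidecar = os.path.join(outdir, "cohort_config.json")
    cohort.config.to_json(sidecar)
    paths["cohort_config.json"] = sidecar
    return paths
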