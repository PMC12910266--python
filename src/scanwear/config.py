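"""Cohort-simulation configuration.

The defaults encode the study conditions of a hereditary-cancer (Li-Fraumeni
syndrome) digital-health cohort: 9 children and 36 adults followed for a
180-day target window, biweekly check-in calls that imprint a ~14-day
engagement cycle, age-group-dependent smartwatch adherence with slow decay
and absorbing dropout, daily-survey completion coupled to watch wear,
periodic psychosocial instruments with planted group differences, and
surveillance-scan events carrying smooth pre-scan physiological signatures.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping


class ConfigurationError(ValueError):
    """Raised when a CohortConfig violates its invariants."""


#: channels emitted by the physiology simulator, in canonical order
PHYSIO_CHANNELS = ("eda", "heart_rate", "hrv", "resp_rate", "temperature")

_VALID_SHAPES = ("flat", "linear", "quadratic", "sigmoid")


def _hazard_for_median(median_days: float) -> float:
    """Per-day geometric dropout hazard whose median time equals ``median_days``."""
    return 1.0 - 0.5 ** (1.0 / median_days)


@dataclass
class CohortConfig:
    """Ground-truth parameters of the synthetic cohort.

    Every downstream stage of the pipeline is tested by recovering one of
    these planted values, so the defaults double as the acceptance-test
    conditions.
    """

    # cohort composition (Table-1-like strata)
    n_children: int = 9
    n_adults: int = 36
    prop_tp53_mut_adults: float = 26 / 36
    prop_cancer_history_child: float = 4 / 9
    prop_cancer_history_adult: float = 10 / 36
    all_children_carriers: bool = True

    # follow-up window and check-in cadence
    horizon_days: int = 180
    checkin_period_days: int = 14
    checkin_amplitude: float = 0.15

    # smartwatch adherence: daily wear probability, decay, dropout
    wear_adherence_mean_adult: float = 0.81
    wear_adherence_mean_child: float = 0.56
    adherence_decay_halflife_days: float = 180.0
    dropout_hazard_adult: float = _hazard_for_median(153.0)
    dropout_hazard_child: float = _hazard_for_median(77.0)
    reentry_prob: float = 0.0  # optional re-entry for state-machine stress tests

    # wear-time magnitudes on worn days (hours); Table-1 analog
    wear_hours_mean_adult: float = 17.6
    wear_hours_sd_adult: float = 3.1
    wear_hours_mean_child: float = 15.7
    wear_hours_sd_child: float = 2.9
    sleep_fraction: float = 0.25  # share of wear falling in the 23:00-07:00 window

    # daily stress survey
    survey_completion_mean_adult: float = 0.65
    survey_completion_mean_child: float = 0.51
    survey_watch_coupling: float = 0.7
    stress_p3_child: float = 0.363
    stress_p3_adult: float = 0.143

    # surveillance scans
    prop_with_scans: float = 17 / 45
    prop_two_scans: float = 9 / 17  # among scanned participants
    scan_interval_days: int = 90

    # pre-scan physiology
    prescan_window_days: int = 3
    prescan_effect_amplitude: float = 1.0
    prescan_shapes: Mapping[str, str] = field(
        default_factory=lambda: {
            "eda": "quadratic",
            "heart_rate": "linear",
            "hrv": "linear",
            "resp_rate": "sigmoid",
            "temperature": "flat",
        }
    )
    physio_noise_sd: float = 1.0
    physio_margin_days: int = 35  # emit minute samples this far before each scan
    missing_rate: float = 0.10
    prescan_missing_boost: float = 0.10  # extra MNAR missingness inside the window

    # psychosocial instruments (planted group means / SDs of totals)
    instrument_period_days: int = 14
    phq9_mean_child: float = 10.0
    phq9_sd_child: float = 5.2
    phq9_mean_adult: float = 4.2
    phq9_sd_adult: float = 4.4
    promis_mean_child: float = 22.7
    promis_sd_child: float = 5.9
    promis_mean_adult: float = 16.5
    promis_sd_adult: float = 5.5
    gad7_mean: float = 5.0
    gad7_sd: float = 4.0
    pss4_mean: float = 6.0
    pss4_sd: float = 3.0
    alert_item9_prob: float = 0.11

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_children": self.n_children,
            "n_adults": self.n_adults,
            "horizon_days": self.horizon_days,
            "checkin_period_days": self.checkin_period_days,
            "scan_interval_days": self.scan_interval_days,
            "prescan_window_days": self.prescan_window_days,
            "instrument_period_days": self.instrument_period_days,
        }
        for name, value in counts.items():
            if int(value) != value or value < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer, got {value!r}")
        if self.horizon_days < 1:
            raise ConfigurationError("horizon_days must be >= 1")
        fractions = {
            "prop_tp53_mut_adults": self.prop_tp53_mut_adults,
            "prop_cancer_history_child": self.prop_cancer_history_child,
            "prop_cancer_history_adult": self.prop_cancer_history_adult,
            "wear_adherence_mean_adult": self.wear_adherence_mean_adult,
            "wear_adherence_mean_child": self.wear_adherence_mean_child,
            "dropout_hazard_adult": self.dropout_hazard_adult,
            "dropout_hazard_child": self.dropout_hazard_child,
            "reentry_prob": self.reentry_prob,
            "survey_completion_mean_adult": self.survey_completion_mean_adult,
            "survey_completion_mean_child": self.survey_completion_mean_child,
            "stress_p3_child": self.stress_p3_child,
            "stress_p3_adult": self.stress_p3_adult,
            "prop_with_scans": self.prop_with_scans,
            "prop_two_scans": self.prop_two_scans,
            "missing_rate": self.missing_rate,
            "prescan_missing_boost": self.prescan_missing_boost,
            "sleep_fraction": self.sleep_fraction,
            "alert_item9_prob": self.alert_item9_prob,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")
        if not -1.0 <= self.survey_watch_coupling <= 1.0:
            raise ConfigurationError("survey_watch_coupling must lie in [-1, 1]")
        if not (self.adherence_decay_halflife_days > 0 or math.isinf(self.adherence_decay_halflife_days)):
            raise ConfigurationError("adherence_decay_halflife_days must be positive")
        for name in ("phq9_sd_child", "phq9_sd_adult", "promis_sd_child", "promis_sd_adult",
                     "gad7_sd", "pss4_sd", "physio_noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for channel, shape in self.prescan_shapes.items():
            if channel not in PHYSIO_CHANNELS:
                raise ConfigurationError(f"unknown physiological channel {channel!r}")
            if shape not in _VALID_SHAPES:
                raise ConfigurationError(
                    f"prescan shape for {channel!r} must be one of {_VALID_SHAPES}, got {shape!r}"
                )
        if int(self.seed) != self.seed:
            raise ConfigurationError("seed must be an integer")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["prescan_shapes"] = dict(self.prescan_shapes)
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
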