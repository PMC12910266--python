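"""End-to-end orchestration: stage runners that communicate only via the
documented delimited-text schemas, plus manifest and report assembly.

Every stage consumes the cohort tables (simulated or user-supplied with the
same schema), writes its own CSV/JSON artifacts into the output directory,
and can be replayed from files alone. ``run_all`` chains the stages and
assembles a markdown report mirroring the study's results structure
(wear-metric table, group tests, retention curves, dominant periods,
psychosocial scores, alerts, per-event additive models).
"""

from __future__ import annotations

import json
import logging
import os
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import CohortConfig
from .cohort import SimulatedCohort, simulate_cohort, write_cohort
from . import engagement as eng
from . import retention as ret
from . import periodicity as per
from . import instruments as ins
from . import gam

log = logging.getLogger("scanwear")

STRATA = ("age_group", "tp53_status", "cancer_history")


class ValidationError(ValueError):
    """Input table violates the documented schema."""


@dataclass
class RunContext:
    outdir: str
    seed: int = 0
    threshold_hours: float = 6.0
    horizon_days: int = 180
    window_days: int = 7
    fft_top_k: int = 3
    min_series_days: int = 28
    gam_window_days: int = 3
    folds: int = 5
    min_scans: int = 2
    min_wear_hours: float = 300.0
    lookback_days: int = 30
    written: list = field(default_factory=list)

    def path(self, name: str) -> str:
        os.makedirs(self.outdir, exist_ok=True)
        p = os.path.join(self.outdir, name)
        self.written.append(p)
        return p


# ---------------------------------------------------------------------------
# input loading and validation

_REQUIRED = {
    "participants": ["participant_id", "age_group", "tp53_status", "cancer_history"],
    "daily": ["participant_id", "day_index", "valid_wear_minutes",
              "sleep_wear_minutes", "awake_wear_minutes", "survey_completed"],
    "scans": ["participant_id", "scan_id", "scan_day", "modality"],
    "physio": ["participant_id", "timestamp_min"],
    "instruments": ["participant_id", "day_index", "instrument", "item_index", "value"],
}


def _validate(df: pd.DataFrame, table: str) -> pd.DataFrame:
    missing = [c for c in _REQUIRED[table] if c not in df.columns]
    if missing:
        raise ValidationError(f"{table}: missing columns {missing}")
    if table == "daily":
        bad = df.index[(df["valid_wear_minutes"] < 0) | (df["valid_wear_minutes"] > 1440)]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
            raise ValidationError(f"daily: valid_wear_minutes out of [0,1440] at line(s) {lines}")
        bad = df.index[df["sleep_wear_minutes"] + df["awake_wear_minutes"]
                       != df["valid_wear_minutes"]]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise ValidationError(f"daily: sleep+awake != valid at line(s) {lines}")
    return df


def load_cohort(indir: str) -> SimulatedCohort:
    """Read the five cohort tables (and config sidecar, if present)."""
    tables = {}
    for name in _REQUIRED:
        path = os.path.join(indir, f"{name}.csv")
        tables[name] = _validate(pd.read_csv(path), name)
    sidecar = os.path.join(indir, "cohort_config.json")
    config = CohortConfig.from_json(sidecar) if os.path.exists(sidecar) else CohortConfig()
    return SimulatedCohort(
        participants=tables["participants"],
        daily=tables["daily"],
        scans=tables["scans"],
        physio=tables["physio"],
        instruments=tables["instruments"],
        config=config,
    )


# ---------------------------------------------------------------------------
# stages


def run_simulate(config: CohortConfig, ctx: RunContext) -> SimulatedCohort:
    cohort = simulate_cohort(config)
    paths = write_cohort(cohort, ctx.outdir)
    ctx.written.extend(paths.values())
    log.info(
        "simulated cohort: %d participants, %d daily rows, %d scans, %d physio rows",
        len(cohort.participants), len(cohort.daily), len(cohort.scans), len(cohort.physio),
    )
    return cohort


def participant_series(cohort: SimulatedCohort, ctx: RunContext):
    """Per participant x modality: active series and its 7-day smoothing."""
    out = {}
    for _, part in cohort.participants.iterrows():
        pid = part["participant_id"]
        sub = cohort.daily[cohort.daily["participant_id"] == pid]
        if sub.empty:
            continue
        for modality in ("watch", "survey"):
            act = eng.active_series(sub, modality, ctx.threshold_hours, ctx.horizon_days)
            out[(pid, modality)] = (act, eng.rolling_smooth(act, ctx.window_days))
    return out


def run_engagement(cohort: SimulatedCohort, ctx: RunContext) -> dict:
    series = participant_series(cohort, ctx)
    rows = []
    for (pid, modality), (act, smooth) in series.items():
        rows.append({
            "participant_id": pid,
            "modality": modality,
            "observed_days": len(act),
            "engagement_rate": eng.engagement_rate(act),
        })
    summary = pd.DataFrame(rows)

    couplings = []
    for pid in cohort.participants["participant_id"]:
        if (pid, "watch") in series and (pid, "survey") in series:
            try:
                r = eng.coupling(series[(pid, "watch")][1], series[(pid, "survey")][1])
            except eng.DataError:
                r = float("nan")
            couplings.append({"participant_id": pid, "coupling_r": r})
    coupling_df = pd.DataFrame(couplings)

    tests = []
    merged = summary.merge(cohort.participants, on="participant_id")
    for modality in ("watch", "survey"):
        for stratum in STRATA:
            sub = merged[merged["modality"] == modality]
            levels = sorted(sub[stratum].astype(str).unique())
            if len(levels) != 2:
                continue
            a = sub.loc[sub[stratum].astype(str) == levels[0], "engagement_rate"]
            b = sub.loc[sub[stratum].astype(str) == levels[1], "engagement_rate"]
            if len(a) < 2 or len(b) < 2:
                continue
            res = eng.welch_t(a, b)
            tests.append({
                "modality": modality, "stratum": stratum,
                "level_a": levels[0], "level_b": levels[1],
                "mean_a": res.group_means[0], "mean_b": res.group_means[1],
                "t": res.t_statistic, "df": res.df, "p": res.p_value,
            })
    tests_df = pd.DataFrame(tests)
    wear_table = eng.wear_time_summary(
        cohort.daily, cohort.participants, ctx.threshold_hours,
        horizon_days=ctx.horizon_days,
    )

    summary.to_csv(ctx.path("engagement_summary.csv"), index=False)
    coupling_df.to_csv(ctx.path("coupling.csv"), index=False)
    tests_df.to_csv(ctx.path("group_tests.csv"), index=False)
    wear_table.to_csv(ctx.path("wear_time_summary.csv"), index=False)
    log.info("engagement: %d participant-modality series, %d group tests",
             len(summary), len(tests_df))
    return {"summary": summary, "coupling": coupling_df, "tests": tests_df,
            "wear_table": wear_table, "series": series}


def run_retention(cohort: SimulatedCohort, ctx: RunContext) -> dict:
    all_records, km_rows, test_rows, median_rows = [], [], [], []
    for modality in ("watch", "survey"):
        records = ret.survival_records(
            cohort.daily, cohort.participants, modality,
            ctx.threshold_hours, ctx.horizon_days,
        )
        all_records.append(records)
        n_events = int(records["event"].sum())
        log.info("retention (%s): %d series; %d exits, %d censored",
                 modality, len(records), n_events, len(records) - n_events)
        for stratum in STRATA:
            for level, grp in records.groupby(records[stratum].astype(str)):
                km = ret.km_fit(grp)
                median_rows.append({
                    "modality": modality, "stratum": stratum, "level": level,
                    "n": len(grp), "median_days": km.median,
                    "iqr_lo": km.iqr[0], "iqr_hi": km.iqr[1],
                    "median_ci_lo": km.median_ci[0], "median_ci_hi": km.median_ci[1],
                })
                curve = km.curve.assign(modality=modality, stratum=stratum, level=level)
                km_rows.append(curve)
            try:
                chi2, df, p = ret.log_rank(records.assign(
                    **{stratum: records[stratum].astype(str)}), stratum)
                test_rows.append({"modality": modality, "stratum": stratum,
                                  "chi2": chi2, "df": df, "p": p})
            except ValueError as err:
                log.warning("log-rank skipped for %s/%s: %s", modality, stratum, err)
    records_df = pd.concat(all_records, ignore_index=True)
    curves_df = pd.concat(km_rows, ignore_index=True)
    medians_df = pd.DataFrame(median_rows)
    tests_df = pd.DataFrame(test_rows)
    records_df.to_csv(ctx.path("survival_records.csv"), index=False)
    curves_df.to_csv(ctx.path("km_curves.csv"), index=False)
    medians_df.to_csv(ctx.path("km_medians.csv"), index=False)
    tests_df.to_csv(ctx.path("logrank_tests.csv"), index=False)
    return {"records": records_df, "curves": curves_df,
            "medians": medians_df, "tests": tests_df}


def run_periodicity(cohort: SimulatedCohort, ctx: RunContext,
                    series=None) -> dict:
    if series is None:
        series = participant_series(cohort, ctx)
    spec_rows, top_rows = [], []
    for (pid, modality), (_, smooth) in series.items():
        values = smooth.to_numpy()
        if len(values) < ctx.min_series_days:
            continue
        spectrum = per.periodogram(values)
        for p_days, mag in zip(spectrum.periods_days, spectrum.magnitudes):
            spec_rows.append({"participant_id": pid, "modality": modality,
                              "period_days": p_days, "magnitude": mag})
        for rank, (p_days, mag) in enumerate(
                per.dominant_periods(spectrum, ctx.fft_top_k), start=1):
            top_rows.append({"participant_id": pid, "modality": modality,
                             "rank": rank, "period_days": p_days, "magnitude": mag})
    spectra = pd.DataFrame(spec_rows)
    dominant = pd.DataFrame(top_rows)
    if len(dominant):
        weeks = dominant["period_days"] / 7.0
        hist = (
            pd.cut(weeks, bins=np.arange(0, 27, 1.0), right=False)
            .value_counts().sort_index().rename_axis("period_weeks_bin")
            .reset_index(name="count")
        )
        hist["period_weeks_bin"] = hist["period_weeks_bin"].astype(str)
    else:
        hist = pd.DataFrame(columns=["period_weeks_bin", "count"])
    spectra.to_csv(ctx.path("spectra.csv"), index=False)
    dominant.to_csv(ctx.path("dominant_periods.csv"), index=False)
    hist.to_csv(ctx.path("period_histogram_weeks.csv"), index=False)
    log.info("periodicity: %d spectra, %d dominant-period rows",
             spectra["participant_id"].nunique() if len(spectra) else 0, len(dominant))
    return {"spectra": spectra, "dominant": dominant, "histogram": hist}


def run_scanxiety(cohort: SimulatedCohort, ctx: RunContext) -> dict:
    eligible = gam.eligible_events(
        cohort.participants, cohort.scans, cohort.daily,
        ctx.min_scans, ctx.min_wear_hours, ctx.lookback_days,
    )
    log.info("scanxiety: %d eligible scans across %d participants",
             len(eligible), eligible["participant_id"].nunique() if len(eligible) else 0)
    fits = {}
    excluded = []
    for _, scan in eligible.iterrows():
        try:
            ds = gam.build_event_dataset(cohort.physio, scan, ctx.gam_window_days)
            ds = gam.mice_impute(ds, seed=ctx.seed)
            ds = gam.transform_features(ds)
            fit = gam.fit_gam(ds, scan_id=scan["scan_id"])
            fit.cv_mse = gam.cross_validate(ds, folds=ctx.folds, seed=ctx.seed)
        except (gam.EventExclusionError, ValueError) as err:
            excluded.append({"scan_id": scan["scan_id"], "reason": str(err)})
            log.warning("scan %s excluded: %s", scan["scan_id"], err)
            continue
        fits[scan["scan_id"]] = fit
        with open(ctx.path(f"gam_fit_{scan['scan_id']}.json"), "w") as fh:
            json.dump(fit.to_dict(), fh, indent=1)

    sim_rows = []
    by_part = {}
    for scan_id, fit in fits.items():
        pid = scan_id.rsplit("_S", 1)[0]
        by_part.setdefault(pid, []).append(fit)
    for pid, part_fits in by_part.items():
        for i in range(len(part_fits)):
            for j in range(i + 1, len(part_fits)):
                shared = set(part_fits[i].features) & set(part_fits[j].features)
                for feature in sorted(shared):
                    r = gam.pdp_similarity(part_fits[i], part_fits[j], feature)
                    sim_rows.append({
                        "participant_id": pid,
                        "scan_a": part_fits[i].scan_id, "scan_b": part_fits[j].scan_id,
                        "feature": feature, "pdp_r": r,
                    })
    similarity = pd.DataFrame(
        sim_rows, columns=["participant_id", "scan_a", "scan_b", "feature", "pdp_r"])
    similarity.to_csv(ctx.path("pdp_similarity.csv"), index=False)
    pd.DataFrame(excluded, columns=["scan_id", "reason"]).to_csv(
        ctx.path("excluded_events.csv"), index=False)
    return {"eligible": eligible, "fits": fits, "similarity": similarity,
            "excluded": excluded}


def run_scores(cohort: SimulatedCohort, ctx: RunContext) -> dict:
    scores = ins.score_table(cohort.instruments)
    alerts = ins.alert_log(cohort.instruments)
    stress_rows = []
    for pid, grp in cohort.daily.groupby("participant_id", sort=True):
        stress_rows.append({"participant_id": pid,
                            "very_stressed_frequency": ins.stress_frequency(grp)})
    stress = pd.DataFrame(stress_rows)
    tests = []
    for stratum in STRATA:
        tests.append(ins.group_compare(scores, cohort.participants, stratum))
    tests_df = pd.concat(tests, ignore_index=True)
    rolling = {
        inst: ins.rolling_score_matrix(scores, inst, horizon_days=ctx.horizon_days)
        for inst in ins.INSTRUMENT_SPECS
    }
    rolling_long = pd.concat(
        [m.reset_index(names="participant_id").melt(
            id_vars="participant_id", var_name="day_index", value_name="rolling_total"
        ).assign(instrument=inst) for inst, m in rolling.items()],
        ignore_index=True,
    ).dropna(subset=["rolling_total"])

    scores.to_csv(ctx.path("scores.csv"), index=False)
    alerts.to_csv(ctx.path("alerts.csv"), index=False)
    stress.to_csv(ctx.path("stress_frequency.csv"), index=False)
    tests_df.to_csv(ctx.path("score_group_tests.csv"), index=False)
    rolling_long.to_csv(ctx.path("rolling_scores.csv"), index=False)
    log.info("scores: %d totals, %d alerts from %d participants",
             len(scores), len(alerts), alerts["participant_id"].nunique() if len(alerts) else 0)
    return {"scores": scores, "alerts": alerts, "stress": stress,
            "tests": tests_df, "rolling": rolling_long}


# ---------------------------------------------------------------------------
# manifest + report


def write_manifest(ctx: RunContext, config: CohortConfig | None, counts: dict) -> str:
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": ctx.seed,
        "thresholds": {
            "threshold_hours": ctx.threshold_hours,
            "horizon_days": ctx.horizon_days,
            "window_days": ctx.window_days,
            "fft_top_k": ctx.fft_top_k,
            "gam_window_days": ctx.gam_window_days,
            "folds": ctx.folds,
            "min_scans": ctx.min_scans,
            "min_wear_hours": ctx.min_wear_hours,
            "lookback_days": ctx.lookback_days,
        },
        "cohort_config": config.to_dict() if config is not None else None,
        "row_counts": counts,
    }
    path = ctx.path("manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def _md_table(df: pd.DataFrame, max_rows: int = 30) -> str:
    if df is None or len(df) == 0:
        return "_(no rows)_\n"
    sub = df.head(max_rows).copy()
    for c in sub.columns:
        if sub[c].dtype.kind == "f":
            sub[c] = sub[c].map(lambda v: f"{v:.4g}")
    header = "| " + " | ".join(map(str, sub.columns)) + " |"
    sep = "|" + "|".join("---" for _ in sub.columns) + "|"
    body = "\n".join("| " + " | ".join(map(str, row)) + " |" for row in sub.to_numpy())
    return "\n".join([header, sep, body]) + "\n"


def write_report(ctx: RunContext, results: dict) -> str:
    parts = ["# Cohort analysis report\n"]
    parts.append("## Wear-time summary (Table-1 analog)\n")
    parts.append(_md_table(results["engagement"]["wear_table"]))
    parts.append("## Engagement group comparisons (Welch)\n")
    parts.append(_md_table(results["engagement"]["tests"]))
    parts.append("## Watch-survey coupling\n")
    r = results["engagement"]["coupling"]["coupling_r"]
    parts.append(f"Median per-participant Pearson r: {np.nanmedian(r):.3f} "
                 f"(n={r.notna().sum()})\n")
    parts.append("## Retention medians and log-rank tests\n")
    parts.append(_md_table(results["retention"]["medians"]))
    parts.append(_md_table(results["retention"]["tests"]))
    parts.append("## Dominant engagement periods (weeks)\n")
    parts.append(_md_table(results["periodicity"]["histogram"]))
    parts.append("## Psychosocial score comparisons\n")
    parts.append(_md_table(results["scores"]["tests"]))
    n_alert = results["scores"]["alerts"]["participant_id"].nunique() \
        if len(results["scores"]["alerts"]) else 0
    parts.append(f"## Self-harm item alerts\n\nParticipants ever alerting: {n_alert}\n")
    parts.append("## Pre-scan additive models\n")
    fits = results["scanxiety"]["fits"]
    parts.append(f"Events modeled: {len(fits)}\n")
    if fits:
        rows = [{"scan_id": f.scan_id, "lambda": f.lambda_, "cv_mse": f.cv_mse}
                for f in fits.values()]
        parts.append(_md_table(pd.DataFrame(rows)))
    parts.append("## Within-person PDP similarity\n")
    parts.append(_md_table(results["scanxiety"]["similarity"]))
    path = ctx.path("report.md")
    with open(path, "w") as fh:
        fh.write("\n".join(parts))
    return path


def run_all(config: CohortConfig, ctx: RunContext) -> dict:
    cohort = run_simulate(config, ctx)
    results = {}
    results["engagement"] = run_engagement(cohort, ctx)
    results["retention"] = run_retention(cohort, ctx)
    results["periodicity"] = run_periodicity(cohort, ctx, results["engagement"]["series"])
    results["scanxiety"] = run_scanxiety(cohort, ctx)
    results["scores"] = run_scores(cohort, ctx)
    counts = {
        "participants": len(cohort.participants),
        "daily": len(cohort.daily),
        "scans": len(cohort.scans),
        "physio": len(cohort.physio),
        "instruments": len(cohort.instruments),
        "alerts": len(results["scores"]["alerts"]),
        "gam_fits": len(results["scanxiety"]["fits"]),
    }
    write_manifest(ctx, config, counts)
    write_report(ctx, results)
    results["cohort"] = cohort
    return results
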