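"""Scan-event dataset construction, chained-equation imputation, feature
transforms and the penalized-spline additive model (including an external
mgcv cross-check)."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from scanwear.gam import (
    AdditiveSplineGAM,
    EventExclusionError,
    build_event_dataset,
    cross_validate,
    eligible_events,
    fit_gam,
    mice_impute,
    pdp_similarity,
    transform_features,
)
from conftest import make_event_dataset


def _daily(pid, days, minutes):
    return pd.DataFrame({
        "participant_id": pid, "day_index": days,
        "valid_wear_minutes": minutes,
        "sleep_wear_minutes": 0, "awake_wear_minutes": minutes,
        "survey_completed": True, "stress_level": 0,
    })


class TestEligibility:
    def _scans(self, pid, days):
        return pd.DataFrame({
            "participant_id": pid, "scan_id": [f"{pid}_S{i}" for i in range(len(days))],
            "scan_day": days, "modality": "MRI",
        })

    def test_single_scan_excluded(self):
        daily = _daily("A", range(60), 1440)
        out = eligible_events(None, self._scans("A", [50]), daily)
        assert out.empty

    def test_wear_boundary(self):
        # 300 h in the 30-day look-back = 18000 min; 17940 min falls short
        scans = self._scans("A", [40, 50])
        ok = _daily("A", range(60), 600)  # 600*30/60 = 300 h exactly
        short = _daily("A", range(60), 598)  # 299 h
        assert len(eligible_events(None, scans, ok)) == 2
        assert eligible_events(None, scans, short).empty

    def test_one_failing_scan_drops_participant(self):
        scans = self._scans("A", [40, 75])
        # heavy wear before day 40 (scan 1 passes), none afterwards (scan 2
        # sees an empty look-back) -> the whole participant is excluded
        daily = _daily("A", list(range(0, 40)), 1440)
        out = eligible_events(None, scans, daily)
        assert out.empty

    def test_default_cohort_shape(self, default_cohort):
        """With the study-shaped generator the eligible set is a handful of
        multiply-scanned, high-wear participants."""
        out = eligible_events(default_cohort.participants, default_cohort.scans,
                              default_cohort.daily)
        n_parts = out["participant_id"].nunique() if len(out) else 0
        assert 1 <= n_parts <= 12


class TestBuildEventDataset:
    def _physio(self, pid, timestamps):
        rng = np.random.default_rng(0)
        n = len(timestamps)
        return pd.DataFrame({
            "participant_id": pid, "timestamp_min": timestamps,
            "eda": rng.lognormal(size=n), "heart_rate": rng.normal(70, 5, n),
            "hrv": rng.lognormal(np.log(50), 0.2, n),
            "resp_rate": rng.normal(14, 1, n), "temperature": rng.normal(33, 0.3, n),
        })

    def test_full_window_row_count(self):
        scan = pd.Series({"participant_id": "A", "scan_id": "A_S0", "scan_day": 3})
        physio = self._physio("A", np.arange(0, 3 * 1440))
        ds = build_event_dataset(physio, scan, window_days=3)
        assert len(ds) == 4320
        assert ds["time_to_scan"].min() > 0

    def test_half_open_boundary(self):
        scan = pd.Series({"participant_id": "A", "scan_id": "A_S0", "scan_day": 1})
        physio = self._physio("A", np.array([1439, 1440]))
        ds = build_event_dataset(physio, scan, window_days=1)
        assert len(ds) == 1  # the sample at the scan instant is excluded
        assert ds["time_to_scan"].iloc[0] == 1.0

    def test_window_nesting(self):
        scan = pd.Series({"participant_id": "A", "scan_id": "A_S0", "scan_day": 3})
        physio = self._physio("A", np.arange(0, 3 * 1440, 7))
        d1 = build_event_dataset(physio, scan, window_days=1)
        d3 = build_event_dataset(physio, scan, window_days=3)
        assert set(d1["timestamp_min"]) <= set(d3["timestamp_min"])

    def test_empty_window_names_scan(self):
        scan = pd.Series({"participant_id": "A", "scan_id": "A_S9", "scan_day": 100})
        with pytest.raises(EventExclusionError, match="A_S9"):
            build_event_dataset(self._physio("A", np.arange(10)), scan)


class TestMice:
    def _correlated(self, n=800, r=0.9, seed=0):
        rng = np.random.default_rng(seed)
        cov = np.array([[1.0, r], [r, 1.0]])
        z = rng.multivariate_normal([0, 0], cov, size=n)
        return pd.DataFrame({"eda": np.exp(z[:, 0]), "heart_rate": 70 + 5 * z[:, 1]})

    def test_identity_when_complete(self):
        df = self._correlated()
        out = mice_impute(df)
        assert (out["missingness_fraction"] == 0).all()
        assert np.array_equal(out["eda"].to_numpy(), df["eda"].to_numpy())
        assert np.array_equal(out["heart_rate"].to_numpy(), df["heart_rate"].to_numpy())

    def test_observed_values_never_altered(self):
        df = self._correlated()
        rng = np.random.default_rng(1)
        mask = rng.random(len(df)) < 0.2
        df.loc[mask, "heart_rate"] = np.nan
        out = mice_impute(df, seed=1)
        assert np.array_equal(out.loc[~mask, "heart_rate"].to_numpy(),
                              df.loc[~mask, "heart_rate"].to_numpy())
        assert out["heart_rate"].notna().all()
        assert np.allclose(out.loc[mask, "missingness_fraction"], 0.5)

    def test_correlated_channels_beat_mean_imputation(self):
        df = self._correlated(r=0.9, seed=2)
        truth = df["heart_rate"].to_numpy().copy()
        rng = np.random.default_rng(2)
        mask = rng.random(len(df)) < 0.2
        df.loc[mask, "heart_rate"] = np.nan
        out = mice_impute(df, seed=2)
        rmse = np.sqrt(np.mean((out.loc[mask, "heart_rate"] - truth[mask]) ** 2))
        mean_rmse = np.sqrt(np.mean((df["heart_rate"].mean() - truth[mask]) ** 2))
        assert rmse < mean_rmse

    def test_independent_channels_match_mean_imputation(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"eda": rng.lognormal(size=800),
                           "heart_rate": rng.normal(70, 5, 800)})
        truth = df["heart_rate"].to_numpy().copy()
        mask = rng.random(len(df)) < 0.2
        df.loc[mask, "heart_rate"] = np.nan
        out = mice_impute(df, seed=3)
        rmse = np.sqrt(np.mean((out.loc[mask, "heart_rate"] - truth[mask]) ** 2))
        mean_rmse = np.sqrt(np.mean((df["heart_rate"].mean() - truth[mask]) ** 2))
        assert rmse == pytest.approx(mean_rmse, rel=0.15)

    def test_fully_missing_channel_excluded(self):
        df = self._correlated(n=50)
        df["eda"] = np.nan
        with pytest.raises(EventExclusionError, match="eda"):
            mice_impute(df)

    def test_sparse_channel_flagged(self):
        df = self._correlated(n=100)
        df.loc[df.index[:90], "eda"] = np.nan
        with pytest.raises(EventExclusionError, match="flagged"):
            mice_impute(df)

    def test_deterministic_under_seed(self):
        df = self._correlated(seed=4)
        rng = np.random.default_rng(4)
        df.loc[rng.random(len(df)) < 0.3, "eda"] = np.nan
        a = mice_impute(df, seed=9)
        b = mice_impute(df, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestTransformFeatures:
    def _dataset(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "eda": rng.lognormal(0, 0.5, n), "heart_rate": rng.normal(70, 5, n),
            "hrv": rng.lognormal(np.log(50), 0.3, n), "resp_rate": rng.normal(14, 1, n),
            "temperature": rng.normal(33, 0.4, n),
            "missingness_fraction": np.zeros(n), "time_to_scan": rng.uniform(1, 100, n),
        })

    def test_zero_mean_unit_sd(self):
        out = transform_features(self._dataset())
        for col in ("log_eda", "heart_rate", "log_hrv", "resp_rate", "temperature"):
            assert out[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert out[col].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_log_removes_lognormal_skew(self):
        from scipy.stats import skew

        df = self._dataset(n=20000, seed=1)
        out = transform_features(df)
        assert abs(skew(out["log_eda"])) < 0.1
        assert abs(skew(np.log(df["eda"]))) < abs(skew(df["eda"]))

    def test_nonpositive_eda_rejected(self):
        df = self._dataset()
        df.loc[0, "eda"] = 0.0
        with pytest.raises(ValueError, match="eda"):
            transform_features(df)

    def test_constant_channel_dropped_with_warning(self):
        df = self._dataset()
        df["temperature"] = 33.0
        with pytest.warns(RuntimeWarning, match="temperature"):
            out = transform_features(df)
        assert "temperature" not in out.columns

    def test_missingness_not_rescaled(self):
        df = self._dataset()
        df["missingness_fraction"] = np.linspace(0, 1, len(df))
        out = transform_features(df)
        assert out["missingness_fraction"].max() == 1.0


class TestAdditiveModel:
    def test_null_model_flat_pdp(self):
        rng = np.random.default_rng(0)
        n = 3000
        ds = pd.DataFrame({"log_eda": rng.normal(size=n),
                           "time_to_scan": rng.uniform(0, 1000, n)})
        fit = fit_gam(ds, scan_id="null", min_rows=100)
        effect = fit.pdp["log_eda"]["effect"].to_numpy()
        assert np.ptp(effect) < 0.15 * ds["time_to_scan"].std()
        mse = cross_validate(ds, folds=5, seed=0)
        assert mse == pytest.approx(ds["time_to_scan"].var(), rel=0.1)

    def test_monotone_recovery_correct_sign(self):
        ds = make_event_dataset("linear", n=4320, noise_sd=0.25, seed=1)
        ds = ds.rename(columns={"feature": "log_eda"})
        fit = fit_gam(ds, scan_id="lin", min_rows=100)
        pdp = fit.pdp["log_eda"]
        lo, hi = np.percentile(ds["log_eda"], [10, 90])
        central = pdp[(pdp["grid"] >= lo) & (pdp["grid"] <= hi)]
        diffs = np.diff(central["effect"])
        # larger feature values occur closer to the scan: effect decreases
        assert (diffs <= 0).mean() > 0.9
        assert central["effect"].iloc[0] > central["effect"].iloc[-1]

    def test_quadratic_curvature_sign(self):
        # low feature noise: E[t|x] approaches the inverse map w(1-sqrt(x)),
        # which is convex; heavy noise would attenuate and flip the central
        # curvature of the true conditional mean itself
        ds = make_event_dataset("quadratic", n=4320, noise_sd=0.1, seed=2)
        ds = ds.rename(columns={"feature": "log_eda"})
        fit = fit_gam(ds, scan_id="quad", min_rows=100)
        pdp = fit.pdp["log_eda"]
        lo, hi = np.percentile(ds["log_eda"], [10, 90])
        central = pdp[(pdp["grid"] >= lo) & (pdp["grid"] <= hi)]
        quad_coef = np.polyfit(central["grid"], central["effect"], 2)[0]
        assert quad_coef > 0

    def test_pdp_affine_invariant_to_response_rescaling(self):
        ds = make_event_dataset("linear", n=2000, noise_sd=0.2, seed=3)
        ds = ds.rename(columns={"feature": "log_eda"})
        fit1 = fit_gam(ds, min_rows=100)
        ds2 = ds.assign(time_to_scan=3.0 * ds["time_to_scan"] + 100.0)
        fit2 = fit_gam(ds2, min_rows=100)
        a = fit1.pdp["log_eda"]["effect"].to_numpy()
        b = fit2.pdp["log_eda"]["effect"].to_numpy()
        assert np.corrcoef(a, (b - 100.0) / 3.0)[0, 1] > 0.999

    def test_min_rows_enforced(self):
        ds = make_event_dataset("linear", n=100)
        ds = ds.rename(columns={"feature": "log_eda"})
        with pytest.raises(EventExclusionError):
            fit_gam(ds, min_rows=500)

    def test_constant_feature_dropped(self):
        ds = make_event_dataset("linear", n=1000, seed=4)
        ds = ds.rename(columns={"feature": "log_eda"})
        ds["missingness_fraction"] = 0.0
        with pytest.warns(RuntimeWarning, match="missingness_fraction"):
            fit = fit_gam(ds, min_rows=100)
        assert "missingness_fraction" in fit.dropped_features

    def test_duplicated_dataset_cv_stable(self):
        ds = make_event_dataset("linear", n=1500, noise_sd=0.3, seed=5)
        ds = ds.rename(columns={"feature": "log_eda"})
        m1 = cross_validate(ds, seed=0)
        m2 = cross_validate(pd.concat([ds, ds], ignore_index=True), seed=0)
        assert m2 == pytest.approx(m1, rel=0.1)

    def test_matches_mgcv_reml_fit(self, tmp_path):
        """Independent oracle: R mgcv P-spline GAM with REML on the same data
        produces near-identical fitted values."""
        rng = np.random.default_rng(0)
        n = 400
        x = rng.uniform(-2, 2, n)
        y = np.sin(1.5 * x) + rng.normal(0, 0.3, n)
        model = AdditiveSplineGAM().fit(pd.DataFrame({"x": x}), y)
        pred = model.predict(pd.DataFrame({"x": x}))
        data = tmp_path / "d.csv"
        out = tmp_path / "f.csv"
        pd.DataFrame({"x": x, "y": y}).to_csv(data, index=False)
        script = (
            f'd <- read.csv("{data}"); suppressMessages(library(mgcv)); '
            f'fit <- gam(y ~ s(x, bs="ps", k=20), data=d, method="REML"); '
            f'write.csv(data.frame(f=fitted(fit)), "{out}", row.names=FALSE)'
        )
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(out)["f"].to_numpy()
        assert np.corrcoef(pred, ref)[0, 1] > 0.999
        assert np.max(np.abs(pred - ref)) < 0.1 * y.std()


class TestPdpSimilarity:
    def _fit(self, seed, shape="quadratic", noise=0.25):
        ds = make_event_dataset(shape, n=2500, noise_sd=noise, seed=seed)
        ds = ds.rename(columns={"feature": "log_eda"})
        return fit_gam(ds, scan_id=f"s{seed}", min_rows=100)

    def test_identical_fits(self):
        fit = self._fit(0)
        assert pdp_similarity(fit, fit, "log_eda") == pytest.approx(1.0)

    def test_same_planted_shape_high_similarity(self):
        a, b = self._fit(1), self._fit(2)
        assert pdp_similarity(a, b, "log_eda") > 0.8

    def test_missing_feature_rejected(self):
        fit = self._fit(3)
        with pytest.raises(KeyError):
            pdp_similarity(fit, fit, "temperature")
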