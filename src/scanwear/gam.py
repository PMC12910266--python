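"""Pre-scan physiology additive modeling ("scanxiety" analysis).

Per surveillance event, minute-level physiological features from the 3 days
before the scan are imputed (chained equations), log/z-transformed, and
regressed on minutes-to-scan with a Gaussian additive model: one penalized
cubic B-spline smooth per feature (the five physiological z-scores plus a
missingness fraction), no interactions. Smoothing strength is shared across
terms and selected by restricted maximum likelihood over a fixed log-spaced
grid; model quality is the mean squared error from row-wise 5-fold
cross-validation, and fitted smooths are summarized as partial-dependence
curves whose within-person similarity across scans can be quantified.

The additive model itself is implemented here (penalized least squares on a
P-spline basis with a second-order difference penalty); the chained-equation
imputation is scikit-learn's IterativeImputer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.interpolate import BSpline

from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.model_selection import KFold

from .config import PHYSIO_CHANNELS

__all__ = [
    "EventExclusionError",
    "GamFit",
    "AdditiveSplineGAM",
    "eligible_events",
    "build_event_dataset",
    "mice_impute",
    "transform_features",
    "FEATURE_COLUMNS",
    "fit_gam",
    "cross_validate",
    "pdp_similarity",
]

#: model features after transformation, in canonical order
FEATURE_COLUMNS = (
    "log_eda",
    "heart_rate",
    "log_hrv",
    "resp_rate",
    "temperature",
    "missingness_fraction",
)

DEFAULT_LAMBDA_GRID = np.logspace(-2.0, 8.0, 16)


class EventExclusionError(RuntimeError):
    """A scan event that cannot enter the model, with the reason attached."""


# ---------------------------------------------------------------------------
# penalized B-spline basis


class _SplineBasis:
    """Cubic B-spline basis on equally spaced knots over the training range,
    with a second-order difference penalty (P-spline)."""

    def __init__(self, x: np.ndarray, n_basis: int = 20, degree: int = 3):
        x = np.asarray(x, dtype=float)
        self.lo, self.hi = float(np.min(x)), float(np.max(x))
        if self.hi <= self.lo:
            raise ValueError("cannot build a spline basis on a constant feature")
        self.n_basis = n_basis
        self.degree = degree
        n_inner = n_basis - degree + 1
        h = (self.hi - self.lo) / (n_inner - 1)
        inner = np.linspace(self.lo, self.hi, n_inner)
        self.knots = np.concatenate(
            [self.lo + h * np.arange(-degree, 0), inner, self.hi + h * np.arange(1, degree + 1)]
        )
        d = np.diff(np.eye(n_basis), n=2, axis=0)  # second-order differences
        self.penalty = d.T @ d

    def design(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()


@dataclass
class GamFit:
    """Fitted per-event model summary."""

    scan_id: str
    features: tuple
    intercept: float
    lambda_: float
    pdp: dict  # feature -> DataFrame(grid, effect)
    cv_mse: float | None = None
    dropped_features: tuple = ()
    model: "AdditiveSplineGAM" = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "scan_id": self.scan_id,
            "features": list(self.features),
            "dropped_features": list(self.dropped_features),
            "intercept": self.intercept,
            "lambda": self.lambda_,
            "cv_mse": self.cv_mse,
            "pdp": {
                f: {"grid": df["grid"].tolist(), "effect": df["effect"].tolist()}
                for f, df in self.pdp.items()
            },
        }


class AdditiveSplineGAM:
    """Gaussian additive model with one cubic P-spline smooth per feature.

    The penalized least-squares problem ``min ||y - Xb||^2 + lambda b'Sb``
    is solved on a log-spaced grid of shared smoothing parameters; the
    restricted (marginal) likelihood of the equivalent mixed model, with the
    error variance profiled out, selects lambda. Basis columns are centered
    on the training sample, so each smooth has exactly zero mean over the
    training rows and the intercept is the response mean.
    """

    def __init__(self, n_basis: int = 20, lambda_grid=None):
        self.n_basis = n_basis
        self.lambda_grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)

    def fit(self, X: pd.DataFrame, y) -> "AdditiveSplineGAM":
        y = np.asarray(y, dtype=float)
        self.feature_names_ = tuple(X.columns)
        n = len(y)
        self.bases_ = {}
        blocks, penalties = [], []
        for name in self.feature_names_:
            col = X[name].to_numpy(dtype=float)
            basis = _SplineBasis(col, self.n_basis)
            b = basis.design(col)
            self.bases_[name] = basis
            blocks.append(b)
            penalties.append(basis.penalty)
        self.col_means_ = [b.mean(axis=0) for b in blocks]
        design = np.hstack([np.ones((n, 1))] + [b - m for b, m in zip(blocks, self.col_means_)])
        p = design.shape[1]
        s0 = np.zeros((p, p))
        offset = 1
        rank = 0
        for pen in penalties:
            k = pen.shape[0]
            s0[offset:offset + k, offset:offset + k] = pen
            rank += np.linalg.matrix_rank(pen)
            offset += k
        m_null = p - rank

        xtx = design.T @ design
        xty = design.T @ y
        yty = float(y @ y)
        best = None
        for lam in self.lambda_grid:
            h = xtx + lam * s0
            try:
                cho = linalg.cho_factor(h + 1e-10 * np.eye(p))
            except linalg.LinAlgError:
                continue
            beta = linalg.cho_solve(cho, xty)
            rss = yty - 2 * beta @ xty + beta @ xtx @ beta
            pen = lam * float(beta @ s0 @ beta)
            logdet_h = 2.0 * np.sum(np.log(np.diag(cho[0])))
            # profiled Gaussian REML score (constants dropped)
            score = (n - m_null) * np.log(max(rss + pen, 1e-300)) - rank * np.log(lam) + logdet_h
            if best is None or score < best[0]:
                best = (score, lam, beta)
        if best is None:
            raise np.linalg.LinAlgError("no smoothing parameter produced a stable fit")
        _, self.lambda_, self.coef_ = best
        self.intercept_ = float(self.coef_[0])
        self.n_obs_ = n
        return self

    def _blocks(self):
        sizes = [self.bases_[f].n_basis for f in self.feature_names_]
        offsets = np.cumsum([1] + sizes)[:-1]
        return dict(zip(self.feature_names_, zip(offsets, sizes)))

    def smooth_on(self, feature: str, grid) -> np.ndarray:
        """Centered smooth contribution f_j evaluated on ``grid``."""
        offset, size = self._blocks()[feature]
        idx = list(self.feature_names_).index(feature)
        b = self.bases_[feature].design(grid) - self.col_means_[idx]
        return b @ self.coef_[offset:offset + size]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.intercept_)
        for f in self.feature_names_:
            out += self.smooth_on(f, X[f].to_numpy(dtype=float))
        return out

    def partial_dependence(self, feature: str, n_grid: int = 100):
        """PDP over the observed feature range: intercept + centered smooth."""
        basis = self.bases_[feature]
        grid = np.linspace(basis.lo, basis.hi, n_grid)
        return grid, self.intercept_ + self.smooth_on(feature, grid)


# ---------------------------------------------------------------------------
# scan-event pipeline operations


def eligible_events(
    participants: pd.DataFrame,
    scans: pd.DataFrame,
    daily: pd.DataFrame,
    min_scans: int = 2,
    min_wear_hours: float = 300.0,
    lookback_days: int = 30,
) -> pd.DataFrame:
    """Scans entering the analysis: participants with >= ``min_scans`` scans,
    each preceded by >= ``min_wear_hours`` of wear inside the look-back window.

    The look-back horizon is a modeling choice (the wear requirement exceeds
    the 3-day modeling window, so it is necessarily a longer lead-in).
    """
    keep = []
    for pid, grp in scans.groupby("participant_id", sort=True):
        if len(grp) < min_scans:
            continue
        wear = daily[daily["participant_id"] == pid]
        ok = True
        for _, scan in grp.iterrows():
            lo = scan["scan_day"] - lookback_days
            window = wear[(wear["day_index"] >= lo) & (wear["day_index"] < scan["scan_day"])]
            if window["valid_wear_minutes"].sum() / 60.0 < min_wear_hours:
                ok = False
                break
        if ok:
            keep.append(grp)
    if not keep:
        return pd.DataFrame(columns=scans.columns)
    return pd.concat(keep, ignore_index=True)


def build_event_dataset(
    physio: pd.DataFrame, scan: pd.Series, window_days: int = 3
) -> pd.DataFrame:
    """Minute rows in the half-open pre-scan window with the time-to-scan
    response (minutes remaining; the scan instant itself is excluded)."""
    scan_minute = int(scan["scan_day"]) * 1440
    window = window_days * 1440
    sub = physio[physio["participant_id"] == scan["participant_id"]]
    mask = (sub["timestamp_min"] >= scan_minute - window) & (sub["timestamp_min"] < scan_minute)
    rows = sub.loc[mask].copy()
    if rows.empty:
        raise EventExclusionError(f"no physiological samples in window for scan {scan['scan_id']!r}")
    rows["time_to_scan"] = (scan_minute - rows["timestamp_min"]).astype(float)
    rows["scan_id"] = scan["scan_id"]
    return rows.reset_index(drop=True)


def mice_impute(
    dataset: pd.DataFrame,
    n_iterations: int = 10,
    seed: int = 0,
    min_observed_fraction: float = 0.2,
) -> pd.DataFrame:
    """Chained-equation imputation of the physiological channels.

    The per-minute ``missingness_fraction`` (imputed channels / 5) is
    recorded *before* imputation; observed values are never altered. Events
    with a fully missing channel, or a channel observed on fewer than
    ``min_observed_fraction`` of minutes, are excluded with the reason in
    the raised :class:`EventExclusionError`.
    """
    out = dataset.copy()
    channels = [c for c in PHYSIO_CHANNELS if c in out.columns]
    values = out[channels].to_numpy(dtype=float)
    observed = np.isfinite(values)
    frac_obs = observed.mean(axis=0)
    for ch, f in zip(channels, frac_obs):
        if f == 0:
            raise EventExclusionError(f"channel {ch!r} fully missing")
        if f < min_observed_fraction:
            raise EventExclusionError(
                f"channel {ch!r} observed on only {f:.1%} of minutes "
                f"(< {min_observed_fraction:.0%}); event flagged, not imputed"
            )
    out["missingness_fraction"] = 1.0 - observed.mean(axis=1)
    if observed.all():
        return out
    imputer = IterativeImputer(
        max_iter=n_iterations,
        initial_strategy="mean",
        sample_posterior=False,
        random_state=seed,
    )
    completed = imputer.fit_transform(values)
    completed[observed] = values[observed]  # guarantee observed values untouched
    out[channels] = completed
    return out


def transform_features(dataset: pd.DataFrame) -> pd.DataFrame:
    """Log-transform EDA and HRV, then z-score each channel within the event.

    EDA and HRV must be strictly positive before the log. Channels that are
    constant within the event cannot be z-scored and are dropped with a
    warning. The missingness fraction is left on its natural [0, 1] scale.
    """
    out = dataset.copy()
    for raw, name in (("eda", "log_eda"), ("hrv", "log_hrv")):
        if raw in out.columns:
            vals = out[raw].to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise ValueError(f"{raw} must be strictly positive before log transform")
            out[name] = np.log(vals)
            out = out.drop(columns=[raw])
    for col in ("log_eda", "heart_rate", "log_hrv", "resp_rate", "temperature"):
        if col not in out.columns:
            continue
        vals = out[col].to_numpy(dtype=float)
        sd = np.nanstd(vals, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"channel {col!r} is constant within event; dropped", RuntimeWarning)
            out = out.drop(columns=[col])
            continue
        out[col] = (vals - np.nanmean(vals)) / sd
    return out


def _feature_frame(dataset: pd.DataFrame):
    present = [c for c in FEATURE_COLUMNS if c in dataset.columns]
    dropped = []
    for c in list(present):
        if dataset[c].nunique() < 2:
            warnings.warn(f"feature {c!r} has no variation; dropped from GAM", RuntimeWarning)
            present.remove(c)
            dropped.append(c)
    if not present:
        raise ValueError("no usable features for GAM fit")
    return dataset[present], tuple(dropped)


def fit_gam(
    dataset: pd.DataFrame,
    scan_id: str | None = None,
    n_basis: int = 20,
    lambda_grid=None,
    min_rows: int = 500,
    n_grid: int = 100,
) -> GamFit:
    """Fit the per-event additive model and extract partial dependence curves."""
    if len(dataset) < min_rows:
        raise EventExclusionError(
            f"only {len(dataset)} rows (< {min_rows}) for scan {scan_id!r}"
        )
    X, dropped = _feature_frame(dataset)
    y = dataset["time_to_scan"].to_numpy(dtype=float)
    model = AdditiveSplineGAM(n_basis=n_basis, lambda_grid=lambda_grid).fit(X, y)
    pdp = {}
    for f in model.feature_names_:
        grid, effect = model.partial_dependence(f, n_grid)
        pdp[f] = pd.DataFrame({"grid": grid, "effect": effect})
    return GamFit(
        scan_id=scan_id or str(dataset.get("scan_id", pd.Series(["?"])).iloc[0]),
        features=model.feature_names_,
        intercept=model.intercept_,
        lambda_=float(model.lambda_),
        pdp=pdp,
        dropped_features=dropped,
        model=model,
    )


def cross_validate(
    dataset: pd.DataFrame,
    folds: int = 5,
    seed: int = 0,
    n_basis: int = 20,
    lambda_grid=None,
) -> float:
    """Row-wise K-fold held-out MSE of the additive model."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(dataset) < folds * 50:
        raise ValueError(f"need at least {folds * 50} rows for {folds}-fold CV")
    X, _ = _feature_frame(dataset)
    y = dataset["time_to_scan"].to_numpy(dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    mses = []
    for train_idx, test_idx in kf.split(X):
        model = AdditiveSplineGAM(n_basis=n_basis, lambda_grid=lambda_grid)
        model.fit(X.iloc[train_idx], y[train_idx])
        pred = model.predict(X.iloc[test_idx])
        mses.append(float(np.mean((y[test_idx] - pred) ** 2)))
    return float(np.mean(mses))


def pdp_similarity(fit_a: GamFit, fit_b: GamFit, feature: str, n_grid: int = 100) -> float:
    """Pearson correlation of two fits' partial-dependence curves for one
    feature, re-evaluated on the intersection of their observed ranges.

    Returns NaN when the ranges are disjoint or either curve is constant.
    """
    for f in (fit_a, fit_b):
        if feature not in f.features:
            raise KeyError(f"feature {feature!r} not in fit {f.scan_id}")
    ba, bb = fit_a.model.bases_[feature], fit_b.model.bases_[feature]
    lo, hi = max(ba.lo, bb.lo), min(ba.hi, bb.hi)
    if hi <= lo:
        warnings.warn(f"disjoint ranges for {feature!r}; similarity undefined", RuntimeWarning)
        return float("nan")
    grid = np.linspace(lo, hi, n_grid)
    ca = fit_a.model.smooth_on(feature, grid)
    cb = fit_b.model.smooth_on(feature, grid)
    if np.ptp(ca) == 0 or np.ptp(cb) == 0:
        warnings.warn(f"constant partial dependence for {feature!r}", RuntimeWarning)
        return float("nan")
    return float(np.corrcoef(ca, cb)[0, 1])
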