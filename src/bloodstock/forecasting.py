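"""Demand models and the rolling-origin-recalibration protocol.

Two forecasters share one evaluation protocol: an L1-penalized linear model
(LASSO, via scikit-learn) and an LSTM network (:mod:`bloodstock.nn`).  Both
predict the summed platelet demand of the next 2 and next 4 days from the
same design matrix.  Models are trained on the first 500 rows, evaluated on
the following 28, then retrained on an expanded span, and so on — every
retraining recalibrates all hyperparameters by 5-fold *blocked*
cross-validation (contiguous, unshuffled folds) minimizing mean squared
error, so temporal order is never broken.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso
from statsmodels.tsa.stattools import adfuller

from bloodstock.features import WEEKDAY_COLUMNS, feature_columns

__all__ = [
    "LassoConfig",
    "FittedLasso",
    "blocked_cv_splits",
    "fit_lasso",
    "coefficient_report",
    "rolling_origin_forecast",
    "naive_pl7_forecast",
    "adf_trend_check",
    "lasso_factory",
]

log = logging.getLogger(__name__)

#: Engineered predictors that bypass the correlation screen.
_ALWAYS_KEEP = set(WEEKDAY_COLUMNS) | {"PL7"}


@dataclass(frozen=True)
class LassoConfig:
    """LASSO tuning setup.

    ``lambda_grid=None`` auto-scales a 100-point log-spaced grid from the
    training data (from lambda_max, the smallest penalty that zeroes every
    coefficient, down four decades).  ``screen_r2`` re-applies the
    r^2 >= threshold correlation screen against platelet use on each
    training span (None disables; use when the matrix was screened
    globally).
    """

    lambda_grid: tuple | None = None
    cv_folds: int = 5
    screen_r2: float | None = 0.2

    def __post_init__(self):
        if self.lambda_grid is not None:
            if len(self.lambda_grid) == 0:
                raise ValueError("lambda_grid must be non-empty")
            if any(l < 0 for l in self.lambda_grid):
                raise ValueError("lambda values must be >= 0")


@dataclass
class FittedLasso:
    """A LASSO fit with coefficients on the original feature scale."""

    kind: str
    features: list
    coef: np.ndarray
    intercept: float
    chosen_lambda: float
    target: str
    train_end: int = 0

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.features].to_numpy(dtype=float)
        return np.clip(X @ self.coef + self.intercept, 0.0, None)


def blocked_cv_splits(n_rows: int, k: int = 5) -> list:
    """Contiguous, order-preserving k-fold partition.

    Rows are split into k consecutive blocks (sizes differing by at most
    one); each fold validates on one block and trains on the rest.  No
    shuffling — temporal adjacency within blocks is preserved.
    """
    if k < 2:
        raise ValueError(f"need at least 2 folds, got {k}")
    if n_rows < k:
        raise ValueError(f"need n_rows >= k, got {n_rows} < {k}")
    blocks = np.array_split(np.arange(n_rows), k)
    splits = []
    for i, val in enumerate(blocks):
        train = np.concatenate([b for j, b in enumerate(blocks) if j != i])
        splits.append((train, val))
    return splits


def _screened_features(train: pd.DataFrame, threshold: float | None) -> list:
    feats = feature_columns(train)
    if threshold is None or "demand" not in train.columns:
        return feats
    u = train["demand"].to_numpy(dtype=float)
    kept = []
    for c in feats:
        if c in _ALWAYS_KEEP:
            kept.append(c)
            continue
        x = train[c].to_numpy(dtype=float)
        if x.std() == 0 or u.std() == 0:
            continue
        r = float(np.corrcoef(x, u)[0, 1])
        if r * r >= threshold:
            kept.append(c)
    return kept


def _auto_lambda_grid(Xs: np.ndarray, y: np.ndarray, n_points: int = 100):
    n = len(y)
    lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / n
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * 1e-4, n_points)


def fit_lasso(
    train: pd.DataFrame, target: str, config: LassoConfig = LassoConfig()
) -> FittedLasso:
    """Fit the L1-penalized demand model on one training span.

    Features are standardized internally (zero mean, unit variance on the
    training span) so a single penalty is meaningful across heterogeneous
    count scales; the tuning parameter is chosen by blocked CV on MSE, and
    coefficients are mapped back to the original scale.
    """
    feats = _screened_features(train, config.screen_r2)
    y = train[target].to_numpy(dtype=float)
    X = train[feats].to_numpy(dtype=float)

    if y.std() == 0 or not feats:
        log.warning("degenerate target or empty feature set: intercept-only fit")
        return FittedLasso("lasso", feats, np.zeros(len(feats)), float(y.mean()),
                           0.0, target, len(train))

    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd_safe

    grid = (
        np.asarray(config.lambda_grid, dtype=float)
        if config.lambda_grid is not None
        else _auto_lambda_grid(Xs, y)
    )
    if len(grid) == 1:
        best_lam = float(grid[0])
    else:
        splits = blocked_cv_splits(len(y), config.cv_folds)
        cv_mse = np.zeros(len(grid))
        for tr, va in splits:
            for i, lam in enumerate(grid):
                m = _lasso(lam).fit(Xs[tr], y[tr])
                resid = y[va] - m.predict(Xs[va])
                cv_mse[i] += np.mean(resid**2)
        best_lam = float(grid[int(np.argmin(cv_mse))])

    m = _lasso(best_lam).fit(Xs, y)
    coef = m.coef_ / sd_safe
    intercept = float(m.intercept_ - (mu * coef).sum() + 0.0)
    return FittedLasso("lasso", feats, coef, intercept, best_lam, target,
                       len(train))


def _lasso(lam: float) -> Lasso:
    # scikit-learn's OLS limit: Lasso(alpha=0) is ill-conditioned, nudge it
    return Lasso(alpha=max(lam, 1e-12), max_iter=20000, tol=1e-8)


def coefficient_report(models: list) -> pd.DataFrame:
    """Mean and SD of coefficients across model iterations.

    A feature screened out in some iteration contributes a 0 coefficient
    there.  The returned frame is sorted by |mean weight| descending and
    carries the mean/SD of the nonzero-coefficient count in
    ``DataFrame.attrs['nonzero_mean'|'nonzero_sd']``.
    """
    if not models:
        raise ValueError("need at least one fitted model")
    if any(m.kind != "lasso" for m in models):
        raise ValueError("coefficient_report only applies to lasso models")
    all_feats = sorted({f for m in models for f in m.features})
    mat = np.zeros((len(models), len(all_feats)))
    nonzero = np.zeros(len(models))
    for i, m in enumerate(models):
        idx = {f: j for j, f in enumerate(all_feats)}
        for f, c in zip(m.features, m.coef):
            mat[i, idx[f]] = c
        nonzero[i] = int((np.asarray(m.coef) != 0).sum())
    report = pd.DataFrame(
        {
            "feature": all_feats,
            "mean_weight": mat.mean(axis=0),
            "sd_weight": mat.std(axis=0),
        }
    )
    report = report.reindex(
        report["mean_weight"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
    report.attrs["nonzero_mean"] = float(nonzero.mean())
    report.attrs["nonzero_sd"] = float(nonzero.std())
    return report


def rolling_origin_forecast(
    model_factory,
    data: pd.DataFrame,
    initial_train: int = 500,
    step: int = 28,
    model_name: str = "model",
) -> pd.DataFrame:
    """Rolling-origin-recalibration evaluation.

    Iteration j trains on rows ``[0, initial_train + j*step)`` and predicts
    rows ``[initial_train + j*step, initial_train + (j+1)*step)``; the
    concatenated predictions cover every evaluation row exactly once and no
    training span ever touches its own evaluation rows.
    ``model_factory(train_df, target)`` must return an object with a
    ``predict(window_df)`` method; it is called separately for the 2- and
    4-day targets at every refit.

    Returns a frame with ``date, p2, p4, y2, y4, demand, model``, one row
    per evaluation day, predictions clamped at 0.
    """
    n = len(data)
    if n <= initial_train + 1:
        raise ValueError(
            f"need more than initial_train+1={initial_train + 1} rows, got {n}"
        )
    rows = []
    start = initial_train
    while start < n:
        stop = min(start + step, n)
        train = data.iloc[:start]
        window = data.iloc[start:stop]
        m2 = model_factory(train, "y2")
        m4 = model_factory(train, "y4")
        p2 = np.clip(np.asarray(m2.predict(window), dtype=float), 0.0, None)
        p4 = np.clip(np.asarray(m4.predict(window), dtype=float), 0.0, None)
        frag = window[["date", "y2", "y4", "demand"]].copy()
        frag["p2"] = p2
        frag["p4"] = p4
        rows.append(frag)
        start = stop
    out = pd.concat(rows, ignore_index=True)
    out["model"] = model_name
    return out[["date", "p2", "p4", "y2", "y4", "demand", "model"]]


def lasso_factory(config: LassoConfig = LassoConfig()):
    """Adapter for :func:`rolling_origin_forecast`."""

    def factory(train: pd.DataFrame, target: str) -> FittedLasso:
        return fit_lasso(train, target, config)

    return factory


def naive_pl7_forecast(data: pd.DataFrame, initial_train: int = 500) -> pd.DataFrame:
    """Seasonal-naive baseline: p2 = 2*PL7, p4 = 4*PL7.

    Scales the trailing-week mean to each horizon; the natural yardstick
    any multivariate model must beat.
    """
    window = data.iloc[initial_train:]
    out = window[["date", "y2", "y4", "demand"]].copy()
    out["p2"] = 2.0 * window["PL7"].to_numpy(dtype=float)
    out["p4"] = 4.0 * window["PL7"].to_numpy(dtype=float)
    out["model"] = "naive_pl7"
    return out[["date", "p2", "p4", "y2", "y4", "demand", "model"]].reset_index(
        drop=True
    )


def adf_trend_check(series) -> tuple:
    """Augmented Dickey-Fuller test with constant + linear trend.

    Checks trend-stationarity of the demand series (required for the
    expanding-window protocol to be meaningful).  Returns
    ``(statistic, p_value, is_trend_stationary)`` with the flag true when
    the unit-root null is rejected at p < .05.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 50:
        raise ValueError("need at least 50 observations")
    if x.std() == 0:
        raise ValueError("ADF test undefined for a constant series")
    stat, pvalue, *_ = adfuller(x, regression="ct", autolag="AIC")
    return float(stat), float(pvalue), bool(pvalue < 0.05)
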